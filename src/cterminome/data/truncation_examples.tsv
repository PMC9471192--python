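gene	accession	annotated_sequence
HSP90AB1	P08238	[K].LGLGIDEDEVAA.[E]
HSP90AB1	P08238	[K].LGLGIDEDEVAAEEPNAAVPD.[E]
HSP90AB1	P08238	[K].LGLGIDEDEVAAEEPNAAVPDEIPPLEGD.[E]
HSP90AB1	P08238	[K].LGLGIDEDEVAAEEPNAAVPDEIPPLEGDED.[A]
HSP90AB1	P08238	[K].LGLGIDEDEVAAEEPNAAVPDEIPPLEGDEDASR.[M]
HSP90AB1	P08238	[K].LGLGIDEDEVAAEEPNAAVPDEIPPLEGDEDASRMEEVD.[-]
H4	P62805	[K].VFLENVIR.[D]
H4	P62805	[K].VFLENVIRD.[A]
H4	P62805	[K].VFLENVIRDA.[V]
H4	P62805	[K].VFLENVIRDAV.[T]
H4	P62805	[K].VFLENVIRDAVTY.[T]
H4	P62805	[K].RQGRTLYGF.[G]
H4	P62805	[K].RQGRTLYGFG.[G]
H4	P62805	[K].RQGRTLYGFGG.[-]
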