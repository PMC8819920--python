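chr14	105586437	106879844	IGH
chr2	88857361	90235368	IGK
chr22	22026076	22922913	IGL
chr14	21621904	22552132	TRA
chr7	142299011	142813287	TRB
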