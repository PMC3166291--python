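rank conf id
1  0.839 YBR109C-F140_GLY_Scer
2  0.831 YBR109C-F140_ASP_Scer
3  0.783 YBR109C-F140_CYS_Scer
4  0.776 YBR109C-F140_PRO_Scer
5  0.769 YBR109C-F140_THR_Scer
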