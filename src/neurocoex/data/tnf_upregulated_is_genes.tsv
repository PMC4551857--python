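gene_id	symbol	categories
ENSRNOG00000007917	Cd46	GO:0006955,GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000011971	C1s	GO:0002376,GO:0006955,GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000014832	Mapkapk3	GO:0002376,GO:0006955,GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000019440	Kcnn4	GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000033134	Mef2c	GO:0006955,GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000033879	Clec7a	GO:0006955,GO:0002682,GO:0002684,GO:0002253
ENSRNOG00000000239	Ccl7	GO:0002376,GO:0006955,GO:0050900,GO:0002682,GO:0002684
ENSRNOG00000004498	Scin	GO:0002682
ENSRNOG00000008409	Myo1f	GO:0002376,GO:0006955,GO:0002682
ENSRNOG00000009912	Fgr	GO:0002376,GO:0006955,GO:0002682,GO:0002684
ENSRNOG00000010906	Ccl5	GO:0002376,GO:0006955,GO:0050900,GO:0002682,GO:0002684
ENSRNOG00000013794	Rbp1	GO:0002682
ENSRNOG00000014333	Vcam1	GO:0002376,GO:0050900,GO:0002682,GO:0002684
ENSRNOG00000015618	Wnt5a	GO:0006955,GO:0050900,GO:0002682,GO:0002684
ENSRNOG00000016294	Cd4	GO:0002376,GO:0006955,GO:0002682,GO:0002684
ENSRNOG00000018659	Csf1	GO:0002376,GO:0006955,GO:0002682
ENSRNOG00000024899	Cxcl13	GO:0002376,GO:0006955,GO:0050900,GO:0002682,GO:0002684
ENSRNOG00000028015	Pf4	GO:0002376,GO:0006955,GO:0050900,GO:0002682
ENSRNOG00000032224	Hist2h4	GO:0002682
ENSRNOG00000008837	Ass1	GO:0002376,GO:0006955
ENSRNOG00000016535	Ccl22	GO:0002376,GO:0006955
ENSRNOG00000022298	Cxcl11	GO:0002376,GO:0006955
ENSRNOG00000026647	Cxcl16	GO:0002376,GO:0006955,GO:0050900
ENSRNOG00000028548	Ccl9	GO:0002376,GO:0006955
ENSRNOG00000028768	LOC100911495	GO:0002376,GO:0006955
ENSRNOG00000031743	Gbp2	GO:0006955
ENSRNOG00000032240	Gbp5	GO:0002376,GO:0006955
ENSRNOG00000017197	Pdgfb	GO:0002376,GO:0050900
ENSRNOG00000043451	Spp1	GO:0002376,GO:0050900
ENSRNOG00000011238	Tiparp	GO:0002376
ENSRNOG00000019494	Psmb10	GO:0002376
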