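# 19 quality-selected MAGs of the BNO deep-underground biofilm metagenome:
# GTDB lineage, bin size (bp, from printed Mb), GC %, gene count, community
# percentage, CheckM completeness and contamination.
# The published table abbreviates lineages; the printed ranks are verbatim
# and the unprinted interior ranks are reconstructed from the standard GTDB
# placement of the printed names (phylum/class assignments as discussed in
# the source study's text).
mag_id	classification	size_bp	gc	genes	percentage	completeness	contamination
MAG1	d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Burkholderiales;f__Nitrosomonadaceae;g__Nitrosomonas;s__	2960000	48.2	3021	21.35	97.13	0.62
MAG5	d__Bacteria;p__Planctomycetota;c__Brocadiia;o__Brocadiales;f__Brocadiaceae;g__;s__	3840000	39.8	4019	1.01	98.9	2.75
MAG6	d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodobacterales;f__Rhodobacteraceae;g__Limibaculum;s__	3870000	68.7	3817	5.48	99.5	0
MAG14	d__Bacteria;p__Cyanobacteria;c__Vampirovibrionia;o__Vampirovibrionales;f__Vampirovibrionaceae;g__;s__	3570000	58.2	3455	1.24	96.58	1.28
MAG15	d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Methylococcales;f__Methylococcaceae;g__Methylocaldum;s__Methylocaldum sp002005105	4960000	58.2	5412	1.68	96.04	4.37
MAG16	d__Bacteria;p__Nitrospirota;c__Nitrospiria;o__Nitrospirales;f__UBA8639;g__;s__	3730000	52.9	4498	0.87	96.74	3.18
MAG17	d__Bacteria;p__Planctomycetota;c__Phycisphaerae;o__Phycisphaerales;f__Phycisphaeraceae;g__UBA5793;s__	4260000	66.9	3804	3.45	94.32	1.14
MAG18	d__Bacteria;p__Myxococcota_A;c__UBA9160;o__UBA9160;f__UBA9160;g__CAADGG01;s__	4690000	70.1	4455	1.86	95.91	1.94
MAG19	d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Xanthomonadales;f__Wenzhouxiangellaceae;g__;s__	2700000	65	2502	40.89	97.1	0.36
MAG20	d__Bacteria;p__Armatimonadota;c__Fimbriimonadia;o__Fimbriimonadales;f__Fimbriimonadaceae;g__J051;s__J051 sp003695835	2580000	61.1	2481	1.45	93.21	2.78
MAG22	d__Bacteria;p__Planctomycetota;c__Phycisphaerae;o__Phycisphaerales;f__Phycisphaeraceae;g__J020;s__	2880000	66.6	2684	7.19	98.86	0
MAG24	d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Legionellales;f__Legionellaceae;g__Tatlockia;s__Tatlockia maceachernii	3310000	40.6	3305	0.66	94.74	3.7
MAG25	d__Bacteria;p__Nitrospirota;c__Nitrospiria;o__Nitrospirales;f__Nitrospiraceae;g__;s__	4420000	62.5	4809	1.68	96.76	5.45
MAG29	d__Bacteria;p__Myxococcota;c__Polyangia;o__Polyangiales;f__SG8-38;g__;s__	7850000	72.1	7619	1.22	97.17	7.9
MAG30	d__Bacteria;p__Planctomycetota;c__Phycisphaerae;o__Phycisphaerales;f__Phycisphaeraceae;g__CAADGN01;s__	3160000	69.7	2949	2.6	100	3.51
MAG37	d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Sphingomonadales;f__Sphingomonadaceae;g__PRO5;s__PRO5 sp003577275	3390000	61	3241	2.38	99.5	0
MAG40	d__Bacteria;p__Planctomycetota;c__Brocadiia;o__Brocadiales;f__Brocadiaceae;g__Kuenenia;s__	3740000	41	4092	1.76	97.8	1.65
MAG41	d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Burkholderiales;f__Nitrosomonadaceae;g__Nitrosomonas;s__	2990000	49.1	3231	1.48	92.51	2.32
MAG42	d__Bacteria;p__Gemmatimonadota;c__Gemmatimonadetes;o__Gemmatimonadales;f__Gemmatimonadaceae;g__SZUA-320;s__	4160000	66.8	4163	1.74	97.8	2.2
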