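# Parchment ZooMS marker panel: sheep (Ovis), goat (Capra), cattle (Bos) and the
# outlier control red deer (Cervus). One row per (marker code, hydroxylation state);
# mass is the monoisotopic [M+H]+ at that state's nH level. The F1 marker is a
# missed-cleavage peptide. The deer G marker carries one more hydroxyproline than
# the sheep/goat/cattle homologues.
code	taxon	sequence	nh_levels	mass
A1	Ovis	TGQPGAVGPAGIR	0	1180.6
A2	Ovis	TGQPGAVGPAGIR	1	1196.6
F1	Ovis	GLTGPIGPPGPAGAPGDKGETGPSGPAGPTGAR	2	2883.4
G1	Ovis	GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR	4	3017.5
G2	Ovis	GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR	5	3033.5
A1	Capra	TGQPGAVGPAGIR	0	1180.6
A2	Capra	TGQPGAVGPAGIR	1	1196.6
F1	Capra	GLTGPIGPPGPAGAPGDKGETGPSGPAGPTGAR	2	2883.4
G1	Capra	GPSGEPGTAGPPGTPGPQGFLGPPGFLGLPGSR	4	3077.5
G2	Capra	GPSGEPGTAGPPGTPGPQGFLGPPGFLGLPGSR	5	3093.5
A1	Bos	IGQPGAVGPAGIR	0	1192.7
A2	Bos	IGQPGAVGPAGIR	1	1208.7
F1	Bos	GLTGPIGPPGPAGAPGDKGEAGPSGPAGPTGAR	2	2853.4
G1	Bos	GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR	4	3017.5
G2	Bos	GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR	5	3033.5
A1	Cervus	TGQPGAVGPAGIR	0	1180.6
A2	Cervus	TGQPGAVGPAGIR	1	1196.6
F1	Cervus	GITGPIGPPGPAGAPGDKGETGPSGPAGPTGAR	2	2883.4
G1	Cervus	GPSGEPGTAGPPGTPGPQGIIGPPGFIGIPGSR	5	3059.5
G2	Cervus	GPSGEPGTAGPPGTPGPQGIIGPPGFIGIPGSR	6	3075.5
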