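carrier_count	hgvs_c	protein	mutation_type	domain	arisen_time_bp	censored	carrier_dates_bp
4	c.3256C>T	p.Arg1086Ter	stopgain	WD40	9860	0	9860,4475,2175,1450
3	c.2257C>T	p.Arg753Ter	stopgain	none	3325	0
3	c.2509G>A	p.Glu837Lys	nonsynonymous SNV	none	7050	0
3	c.2834+1G>A		splice site	WD40	6319	0
2	c.212-1G>A		splice site	ETGE	2275	0
2	c.211+1G>A		splice site	ETGE	10050	0
2	c.1042C>T	p.Gln348Ter	stopgain	none	6319	0
2	c.1117G>T	p.Glu373Ter	stopgain	none	3157	0
2	c.1240C>T	p.Arg414Ter	stopgain	ChAM	3740	0
2	c.1837C>T	p.Gln613Ter	stopgain	none	32895	0
2	c.2218C>T	p.Gln740Ter	stopgain	none	8315	0
2	c.2512C>T	p.Gln838Ter	stopgain	none	3871	0
2	c.2515-1G>A		splice site	none	4106	0
2	c.2630G>A	p.Trp877Ter	stopgain	WD40	5677	0
2	c.2693G>A	p.Trp898Ter	stopgain	WD40	10000	1
2	c.3523C>T	p.Gln1175Ter	stopgain	WD40	6713	0
1	c.3G>A	p.Met1Ile	startloss	none	31630	0
1	c.48+1G>C		splice site	coiled-coil	30260	0
1	c.49-1G>A		splice site	coiled-coil	689	0
1	c.103delC	p.Leu35PhefsTer18	frameshift deletion	coiled-coil	2758	0
1	c.173dupT	p.Leu58PhefsTer16	frameshift insertion	none	2554	0
1	c.178C>T	p.Gln60Ter	stopgain	none	6750	0
1	c.196C>T	p.Gln66Ter	stopgain	none	4158	0
1	c.428delT	p.Leu143ArgfsTer34	frameshift deletion	none	7178	0
1	c.451C>T	p.Gln151Ter	stopgain	none	8790	0
1	c.535C>T	p.Gln179Ter	stopgain	none	4885	0
1	c.940C>T	p.Gln314Ter	stopgain	none	1613	0
1	c.1027C>T	p.Gln343Ter	stopgain	none	2255	0
1	c.1174G>T	p.Glu392Ter	stopgain	none	4161	0
1	c.1257C>A	p.Cys419Ter	stopgain	ChAM	3900	0
1	c.1258C>T	p.Gln420Ter	stopgain	ChAM	725	0
1	c.1378C>T	p.Gln460Ter	stopgain	none	3440	0
1	c.1592delT	p.Leu531CysfsTer30	frameshift deletion	none	700	0
1	c.1969G>T	p.Glu657Ter	stopgain	none	2500	0
1	c.2066C>T	p.Ser689Leu	nonsynonymous SNV	none	6850	0
1	c.2386G>T	p.Gly796Ter	stopgain	none	1506	0
1	c.2389C>T	p.Gln797Ter	stopgain	none	4862	0
1	c.2594C>T	p.Ser865Leu	nonsynonymous SNV	WD40	4940	0
1	c.2674G>T	p.Glu892Ter	stopgain	WD40	8570	0
1	c.2674G>A	p.Glu892Lys	nonsynonymous SNV	WD40	3740	0
1	c.2694G>A	p.Trp898Ter	stopgain	WD40	10000	1
1	c.2761C>T	p.Gln921Ter	stopgain	WD40	2478	0
1	c.2950dupC	p.Leu984ProfsTer3	frameshift insertion	WD40	7221	0
1	c.2962C>T	p.Gln988Ter	stopgain	WD40	1300	0
1	c.3058C>T	p.Gln1020Ter	stopgain	WD40	1246	0
1	c.3114-1G>A		splice site	WD40	2279	0
1	c.3113+1G>A		splice site	WD40	1646	0
1	c.3420G>A	p.Trp1140Ter	stopgain	WD40	1246	0
1	c.3469C>T	p.Gln1157Ter	stopgain	WD40	8315	0
1	c.3492G>A	p.Trp1164Ter	stopgain	WD40	18720	0
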