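# Constituent characterization of a commercial grape seed extract (GSE-1) by UHPLC-UV-CAD-HRMS.
# One row per identified component; co-eluting components under one CAD peak share the peak id
# and the per-dose amount is reported once per CAD peak (first sub-row). The 39th "peak" is the
# broad polymeric-tannin hump (15-45 min). Dose basis: 210 mg extract per day.
cad_peak,sub,rt_min,identification,formula,amount_ug_per_dose,confidence
1,a,1.04,Magnesium salts,,700,partial
1,b,1.04,Calcium salts,,,partial
2,a,1.18,Sodium salts,,4600,partial
2,b,1.18,Potassium salts,,,partial
3,a,1.37,Monosaccharide,C6H12O6,16000,matched
3,b,1.37,Gluconic Acid,C6H12O7,,matched
3,c,1.37,Glutamic Acid,C5H9NO4,,reference
3,d,1.37,Choline hexoside,C11H23NO6,,tentative
3,e,1.37,Arginyl fructose,C12H24N4O7,,tentative
3,f,1.37,Cellobiosan,C12H20O10,,partial
3,g,1.37,Isovaline,C5H11NO2,,matched
4,a,1.53,Tartaric Acid,C4H6O6,5700,matched
4,b,1.53,Disaccharide,C12H22O11,,matched
4,c,1.53,Proline,C5H9NO2,,reference
4,d,1.53,N-methylnicotinate,C7H7NO2,,matched
5,a,2.17,Malic Acid,C4H6O5,1700,reference
5,b,2.17,Unidentified,,,unknown
6,a,4.46,Citric Acid,C6H8O7,51,reference
6,b,4.46,Pyroglutamic Acid,C6H8O7,,matched
7,a,5.56,Succinic Acid,C4H6O4,540,reference
7,b,5.56,Tyrosine,C9H11NO3,,reference
7,c,5.56,Uridine,C9H12N2O6,,matched
7,d,5.56,5'-O-(beta-D-Glucopyranosyl) pyridoxine,C14H21NO8,,tentative
7,e,5.56,Adenosine,C10H14N5O4,,matched
7,f,5.56,Leucine-Fructose,C12H23O7,,tentative
7,g,5.56,Unidentified,C9H16O8,,partial
7,h,5.56,Unidentified,C9H18O8,,partial
7,i,5.56,Unidentified,C10H14O8N2,,partial
7,j,5.56,Unidentified,C11H21N2O3,,partial
7,k,5.56,Unidentified,C12H21N2O3,,partial
7,l,5.56,Unidentified,C19H12N3O2,,partial
8,,9.46,Gallic acid,C7H6O5,210,reference
9,a,13.39,Glucogallin,C13H16O10,180,matched
9,b,13.39,Unidentified,,,unknown
10,,16.39,Tryptophan,C11H12N2O2,92,reference
11,,18.62,Proanthocyanidin B1,C30H26O12,1400,reference
12,,19.02,Proanthocyanidin B,C30H26O12,110,matched
13,,19.57,Proanthocyanidin B,C30H26O12,510,matched
14,,20.25,Catechin,C15H14O6,4100,reference
15,a,20.57,Proanthocyanidin B,C30H26O12,83,matched
15,b,20.57,Gallocatechin Gallate isomer,C22H18O11,,tentative
15,c,20.57,Unidentified,,,unknown
16,,20.69,Proanthocyanidin C,C45H38O18,180,matched
17,,21.01,Benzyl alcohol,C18H26O10,97,tentative
18,,21.14,Galloylated Proanthocyanidin (tetramer),C67H54O28,120,matched
19,,21.82,Proanthocyanidin B2,C30H26O12,1700,reference
20,a,22.39,Proanthocyanidin B,C30H26O12,180,matched
20,b,22.39,Lariciresinol Glucoside analog,C26H34O11,,tentative
20,c,22.39,Unidentified,C13H14O3,,partial
21,,22.73,Proanthocyanidin B,C30H26O12,87,matched
22,,23.02,Epicatechin,C15H14O6,3500,reference
23,a,23.36,"1-(3',4'-dihydroxyphenyl)-3-(2'',4'',6''-trihydroxyophenyl)propan-2-ol",C15H16O6,180,matched
23,b,23.36,Dihydrokaempferol 3-O-beta-D-glucoside,C21H22O11,,matched
24,a,23.54,Epigallocatechin Gallate,C22H18O11,270,reference
24,b,23.54,Galloylated Proanthocyanidin (dimer),C37H30O16,,matched
24,c,23.54,Proanthocyanidin (tetramer),C60H50O24,,matched
25,,23.99,Proanthocyanidin C,C45H38O18,240,matched
26,a,24.24,Proanthocyanidin C1,C45H38O18,890,reference
26,b,24.24,Leptolepisol D,C27H32O10,,tentative
27,a,24.94,Proanthocyanidin B,C30H26O12,230,matched
27,b,24.94,Galloylated Proanthocyanidin (trimer),C52H42O22,,matched
28,a,25.07,Galloylated Proanthocyanidin (dimer),C37H30O16,950,matched
28,b,25.07,Proanthocyanidin (tetramer),C60H50O24,,matched
29,a,25.30,Galloylated Proanthocyanidin (trimer),C52H42O22,85,matched
29,b,25.30,Lariciresinol Glucosides analog,C26H34O11,,tentative
30,a,25.91,Galloylated Proanthocyanidin (trimer),C52H42O22,240,matched
30,b,25.91,Proanthocyanidin (pentamer),C75H62O30,,matched
31,,26.32,Proanthocyanidin B,C30H26O12,93,matched
32,a,27.37,Galloylated Proanthocyanidin (trimer),C52H42O22,110,matched
32,b,27.37,Rutin,C27H30O16,,reference
32,c,27.37,Galloylated Proanthocyanidin (dimer),C44H34O20,,matched
32,d,27.37,"2-(3,4-dihydroxyphenyl)-4-(3-(3-(3,4-dihydroxyphenyl)-2-hydroxypropyl)-2,4,6-trihydroxylphenyl) chromane-3,5,7-triol",C30H28O12,,tentative
32,e,27.37,Methylated Proanthocyanidin B-type analog,C31H28O12,,tentative
33,a,28.00,Epicatechin gallate,C22H18O10,320,reference
33,b,28.00,Proanthocyanidin B,C30H26O12,,matched
34,a,28.41,Catechin gallate,C22H18O10,100,reference
34,b,28.41,Galloylated Proanthocyanidin (trimer),C52H42O22,,matched
34,c,28.41,Embigenin,C23H24O10,,tentative
35,,66.70,Ursolic Acid,C30H48O3,690,tentative
36,,67.04,Linoleic Acid,C18H32O2,200,matched
37,,68.37,Palmitic Acid,C16H32O2,170,matched
38,,68.66,Oleic Acid,C18H34O2,110,matched
39,,,Tannins,,160000,matched
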