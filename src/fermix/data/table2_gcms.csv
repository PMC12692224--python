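category,ri_observed,ri_literature,name,formula,WJ,FWJ-SL05,FWJ-SL08,FWJ-002,FWJ-Mix,threshold,vip
aldehyde,887,887,Nonanal,C9H18O,0.19,0.06,0.03,0.04,0.01,,
aldehyde,900,900,Benzeneacetaldehyde,C8H8O,0.02,ND,ND,ND,ND,,
aldehyde,940,943,Benzaldehyde,C7H6O,0.42,0.20,0.21,0.19,0.24,,
terpene,877,877,D-Limonene,C10H16,0.20,0.25,0.22,0.29,0.34,,
terpene,858,858,γ-Terpinene,C10H16,0.03,0.04,0.04,0.04,0.19,,
terpene,908,908,β-Phellandrene,C10H16,2.32,3.16,3.18,3.37,3.45,,
terpene,893,893,α-Pinene,C10H16,0.83,1.39,1.01,1.23,1.45,,
terpene,905,905,α-Phellandrene,C10H16,0.68,1.03,1.06,1.06,1.22,,
terpene,912,912,(+)-4-Carene,C10H16,0.10,0.18,0.17,0.19,0.25,,
ketone,843,843,2-Pentanone,C5H10O,0.36,ND,ND,ND,ND,,
ketone,889,889,"2,3-Butanedione",C4H6O2,ND,0.13,0.12,0.11,0.13,,
ketone,916,916,"2-Propanone, 1-hydroxy-",C3H6O2,ND,ND,ND,0.41,0.23,,
ketone,963,963,Acetoin,C3H6O,0.06,ND,ND,ND,ND,,
alcohol,883,883,Phenylethyl Alcohol,C8H10O,0.3,ND,ND,0.1,ND,,
alcohol,923,923,Ethanol,C2H6O,ND,3.11,3.02,2.94,3.18,,
alcohol,863,863,"3-Hexen-1-ol, (E)-",C6H12O,ND,0.15,0.17,0.12,0.56,,
alcohol,984,984,2-Propen-1-ol,C3H6O,ND,0.08,0.07,0.02,0.09,,
alcohol,917,917,"Benzenepropanol, 4-methyl-",C10H14O,ND,0.32,0.27,0.29,0.36,,
alcohol,914,914,"1-Hexanol, 2-ethyl-",C8H18O,0.24,0.35,0.39,0.28,0.38,,
alcohol,924,924,1-Heptanol,C7H16O,1.06,1.17,1.26,1.09,1.13,,
alcohol,903,903,"1-Butanol, 3-methyl-",C5H12O,ND,0.36,0.27,0.43,0.34,,
alcohol,834,855,1-Butanol,C4H10O,ND,0.09,0.11,0.14,0.15,,
alcohol,904,904,"3-Buten-2-ol, 2,3-dimethyl-",C6H12O,0.07,0.11,0.12,0.14,0.13,,
alcohol,863,863,"1-Hexyn-3-ol, 3-methyl-",C7H12O,ND,ND,ND,ND,0.56,,
alcohol,854,854,α-Terpineol,C10H18O,0.31,0.63,0.79,0.66,0.84,,
ester,906,906,"Verbenyl angelate, cis-",C15H22O2,0.07,ND,ND,0.03,0.02,,
ester,902,902,Propyl pyruvate,C6H10O3,ND,0.63,0.55,ND,0.44,,
ester,822,822,"Carbonic acid, methyl pentyl ester",C7H14O3,ND,1.97,1.59,0.98,2.43,,
ester,850,852,"Propanoic acid, ethenyl ester",C5H8O2,ND,ND,ND,0.56,0.31,,
ester,999,999,"Acetic acid, methyl ester",C3H6O2,ND,1.39,1.16,1.98,2.37,,
ester,806,806,Ethyl mandelate,C10H12O3,0.11,ND,ND,ND,0.43,,
ester,864,864,"Acetic acid, 2-(methylaminoethyl) ester",C5H11NO2,ND,ND,ND,ND,0.13,,
ester,949,949,Acetic acid ethenyl ester,C4H6O2,ND,0.13,0.11,ND,0.13,,
ester,898,898,"Oxalic acid, butyl cyclobutyl ester",C10H16O4,0.09,0.42,0.38,0.39,0.42,,
ester,995,995,Isopropyl pyruvate,C6H10O3,ND,0.10,ND,ND,0.11,,
ester,916,916,"Butanoic acid, methyl ester",C5H10O2,ND,0.05,0.03,0.03,0.05,,
ester,986,986,n-Propyl acetate,C5H10O2,0.03,0.04,0.05,ND,0.05,,
ester,824,824,"Hexanoic acid, methyl ester",C7H14O2,ND,ND,ND,ND,0.05,,
ester,878,878,"Oxalic acid, dipropyl ester",C8H14O4,0.02,ND,ND,ND,ND,,
acid,955,955,Acetic acid,C2H4O2,3.38,4.34,4.33,4.09,4.47,,
acid,917,917,"Acetic acid, diethyl-",C6H12O2,ND,0.04,0.05,0.05,0.08,,
acid,883,883,Benzeneacetic acid,C8H8O2,ND,0.01,0.03,0.03,0.06,,
acid,827,827,Pentanoic acid,C5H10O2,ND,0.18,0.12,0.11,0.14,,
acid,806,806,5-Aminovaleric acid,C5H11NO2,ND,0.05,0.08,0.09,0.08,,
furan,887,887,2-Acetyl-2-methyltetrahydrofuran,C7H12O2,0.09,0.16,0.17,0.18,0.31,,
furan,933,935,"Furan, 2-methoxy-",C5H6O2,0.13,ND,ND,ND,ND,,
furan,846,846,"Furan, 2,5-dihydro-3-methyl-",C5H8O,0.39,ND,ND,ND,ND,,
furan,840,840,2-Ethyltetrahydrofuran,C6H12O,ND,0.08,0.06,0.08,0.09,,
hydrocarbon,929,929,Decane,C10H22,0.21,0.22,0.23,ND,ND,,
hydrocarbon,856,856,Undecane,C11H24,0.1,0.1,0.1,ND,ND,,
hydrocarbon,846,846,"Undecane, 4,7-dimethyl-",C13H28,ND,0.21,0.2,0.21,0.43,,
hydrocarbon,868,868,"Undecane, 3,5-dimethyl-",C13H28,0.46,ND,ND,ND,0.29,,
hydrocarbon,826,826,Dodecane,C12H26,0.20,0.20,0.20,0.12,0.11,,
hydrocarbon,867,867,"Dodecane, 2,7,10-trimethyl-",C15H32,ND,0.45,0.41,0.43,0.49,,
hydrocarbon,918,918,"2,3-Dimethyldecane",C12H26,ND,ND,ND,0.23,ND,,
hydrocarbon,805,805,Tetradecane,C14H30,ND,0.47,0.57,ND,ND,,
other,922,922,"Phenol, 4-ethyl-",C8H10O,ND,0.29,0.28,0.27,0.49,,
other,883,883,"Phenol, 3-ethyl-",C8H10O,ND,ND,ND,0.13,ND,,
other,907,907,Phenol,C6H6O,0.17,0.13,0.11,0.14,0.18,,
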