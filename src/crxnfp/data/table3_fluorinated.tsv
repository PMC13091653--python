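reaction	ec_reference	claire	theia	crxnfp
5-fluorouracil reduction to 5,6-dihydrofluorouracil	1.3.1.2	1.16.1	1.3.1	1.3.1.2
5,6-dihydrofluorouracil hydrolysis to 2-fluoro-3-ureidopropionic acid	3.5.2.2	1.3.7	3.5.2	3.5.2.2
2-fluoro-3-ureidopropionic acid hydrolysis to 3-amino-2-fluoropropanoic acid	3.5.1.6	5.1.3	3.5.1	3.5.1.6
3-amino-2-fluoropropanoic acid defluorination to 3-aminopropanoic acid	3.8.1.2	3.5.1	3.2.1	3.8.1.3
fluoroacetate defluorination to glycolate	3.8.1.3 AND 3.8.1.2	1.1.1	3.8.1	3.8.1.3
difluoroacetate defluorination to 2-fluoro-2-hydroxyacetate	3.8.1.3 AND 3.8.1.2	1.1.1	3.1.1	3.8.1.3
pentafluoro(trifluoromethyl)pentenoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.-
nonafluorohexenoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.-
tridecafluorooctenoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.-
caffeate CoA ligation	6.2.1	2.8.2	6.2.1	6.2.1.-
caffeoyl-CoA reduction to hydrocaffeoyl-CoA	1.3.1.108	5.1.3	1.3.1	1.3.1.108
pentafluorohexanoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.40
trifluoropropanoic acid CoA ligation	6.2.1	5.1.3	6.2.1	6.2.1.40
trifluoropentanoic acid CoA ligation	6.2.1	2.1.1	2.3.1	6.2.1.40
trifluoropentenoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.40
pentafluoropentanoic acid CoA ligation	6.2.1	1.16.1	2.3.1	6.2.1.40
pentafluoro(trifluoromethyl)pentenoyl-CoA reduction	1.3.1.108	5.1.3	1.18.1	1.3.1.108
nonafluorohexenoyl-CoA reduction	1.3.1.108	5.1.3		1.3.1.108
tetrafluoro(trifluoromethyl)hexenoyl-CoA reduction	1.3.1.108	1.3.1		1.3.1.108
tridecafluorooctenoyl-CoA reduction	1.3.1.108	5.1.3		1.3.1.108
paracetamol amide hydrolysis to 4-aminophenol	3.5.1.13	2.1.1	3.5.1	3.5.1.135
DEET amide hydrolysis to 3-methylbenzoic acid	3.5.1	6.3.4	3.1.1
N,N-dimethyl 4-chlorobenzamide hydrolysis to 4-chlorobenzoic acid	3.5.1	2.1.1	3.1.1
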