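name,observed,predicted
Dicofol,-0.2,0.16
"1,1,2,2-Tetrachloroethane",-2.45,-3.18
"1,1-Dichloroethane",-4.883,-3.32
"1,1,2-Trichloroethane",-5.08,-4.77
"1,2-Diphenylhydrazine",-5.16,-3.66
1-Bromopropane,-7.21,-7.38
Tefluthrin,-2.38,-2.34
"1,2,4-Trichlorobenzene",-1.219,-2.15
Benzo[e]pyrene,0.64,0.08
"2,4-Dichlorophenoxyacetic acid",-2.478,-2.82
Dapsone,-2.507,-2.29
Pyrene,-4.71,-4.55
Styrene,-2.92,-3.36
Hexachlorobutadiene,-3.26,-3.39
Alprazolam,-3.48,-2.67
Prochlorperazine,-4.19,-4.32
Meperidine,-3.27,-3.74
Imipramine,-2.77,-2.86
Metharbital,-4.92,-4.17
Cimetidine,-1.75,-1.38
Procaine,-3.18,-2.85
Diazepam,-3.752,-3.83
Nitrazepam,-2.635,-2.14
Strychnine,-4.4,-4.63
Bromadiolone,-3.54,-2.72
Pentane,-3.96,-4.22
"2,3-Dimethylpentane",-2.144,-1.88
"3,3-Dimethylpentane",-5.666,-6.28
"2,2,3-Trimethylbutane",-1.89,-2.59
2-Methylheptane,-4.61,-3.79
2-Pentene,-2.617,-3.10
2-Methyl-1-butene,-2.73,-2.30
Isopropylbenzene,-5.28,-4.12
2-Nitrophenol,-4.23,-4.12
4-Aminophenol,-8.23,-8.11
Benfluralin,-7.8,-8.11
Chlorpyrifos-methyl,-0.77,-3.38
Iprodione,-6.74,-6.66
Niclosamide,-8.65,-7.77
Oxadiazon,-2.7,-1.57
Prometon,-3.28,-2.78
4-Phenylphenol,-6.8,-6.62
Propylparaben,-2.09,-2.91
Adenine,-2.338,-3.27
Cholic acid,-1.74,-1.90
D-Fructose,-1.29,-1.25
L-Tryptophan,-4.7,-4.58
Succinic acid,-3.42,-3.12
Atrazine,-4.376,-3.61
Clomazone,-4.38,-4.89
Diphenylamine,-2.75,-2.52
Ethofumesate,-2.48,-2.31
Ethylenethiourea,-8.19,-8.14
Fenarimol,-4.28,-3.98
3-Chlorobiphenyl,-2.82,-2.57
Oryzalin,-1.73,-1.61
Picloram,-4.88,-4.81
Terbacil,-1.57,-2.18
Dodecanoic acid,-4.36,-3.95
Equilin,-1.74,-1.24
Griseofulvin,-7.321,-5.84
Estrone,-1.35,-2.85
Hydroxyurea,-3.59,-3.96
1-Hexadecanol,-8.6,-6.74
Coumarin,-6.19,-2.71
Benzoin,-3.51,-3.54
1-Nitronaphthalene,1.12,0.63
"2,3',4,4'-Tetrachlorobiphenyl",-2.82,-3.01
"2,2',3,4,5-Pentachlorobiphenyl",-3.32,-3.24
"1,2-Dibromo-3-chloropropane",-1.89,-2.23
"2,2',3,3',6,6'-Hexachlorobiphenyl",-0.8,-0.24
Vinyl chloride,-5.53,-5.45
Tetracene,-3.6,-4.18
Triphenylene,-2.23,-1.69
Dichlorprop,-5.69,-4.66
2-Methyl-4-chlorophenoxyacetic acid,-3.85,-2.90
Alachlor,-3.8,-3.58
Amygdalin,-1.4,-2.25
Mirex,-2.183,-2.11
Asulam,-7.8,-6.72
Benfuracarb,-4.62,-4.01
Benomyl,-4.45,-7.01
Carbaril,-2.54,-2.51
Chlorbufam,-7.26,-5.66
"2,4-Dinitrophenol",-2.85,-3.21
Dioxacarb,-3.37,-4.22
Benzo[a]pyrene,-4.82,-4.75
Pyrolan,-1.48,-1.47
Ethylbenzene,-0.71,-0.76
Benzo[b]fluoranthene,-1.66,-2.38
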