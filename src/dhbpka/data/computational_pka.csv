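compound,substituent,pka_ohm,pka_ohp,pka_rh,sigma_p
4-Tert-butylcatechol,tert-butyl,8.24,13.51,,-0.2
4-Methylcatechol,methyl,9.23,13.33,,-0.17
4-Ethylcatechol,ethyl,8.29,13.42,,-0.15
"3,4-Dihydroxydihydrocinnamic acid",2-carboxyethyl,6.83,11.76,4.88,-0.07
"3,4-Dihydroxyphenylacetic acid",carboxymethyl,10.09,12.07,4.98,
Catechol,H,8.82,13.07,,0
Norepinephrine,2-amino-1-hydroxyethyl,13.41,8.59,10.41,0.09
"1,2,4-Benzenetriol",hydroxyl,9.26,11.13,12.60,-0.37
Caffeic acid,2-carboxyvinyl,12.50,8.50,3.92,0.09
Dopamine,2-aminoethyl,13.7,8.66,11.01,0.17
4-Chlorocatechol,chloro,8.13,10.41,,0.23
Epinephrine,1-hydroxy-2-(methylamino)ethyl,13.08,8.65,10.89,0.3
"3,4-Dihydroxybenzaldehyde",formyl,11.78,8.71,,0.42
"3,4-Dihydroxybenzoic acid",carboxyl,11.79,9.11,3.22,0.45
"3,4-Dihydroxybenzylamine",aminomethyl,13.07,5.62,9.01,0.53
"3,4-Dihydroxybenzonitrile",cyano,11.79,6.54,,0.66
4-Nitrocatechol,nitro,11.15,6.10,,0.78
Adrenalone,(methylamino)acetyl,11.96,5.16,7.24,
Dopa,2-amino-2-carboxyethyl,13.6,8.86,2.31/10.2,
Catechin,"3,5,7-trihydroxychroman-2-yl",8.61,9.38,11.61,
Quercetin,"3,5,7-trihydroxy-4-oxochromen-2-yl",6.78,11.56,9.17,
Chlorogenic acid,2-(quinoyloxycarbonyl)vinyl,11.53,8.11,3.43,
Isoprenaline,1-hydroxy-2-(isopropylamino)ethyl,8.52,10.06,,
Nordihydroguaiaretic acid,"4-(3,4-dihydroxyphenyl)-2,3-dimethylbutyl",9.30,14.31,,
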