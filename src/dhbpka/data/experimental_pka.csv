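compound,pka1,pka1_sd,pka2,pka2_sd,pka3,pka3_sd
4-Tert-butylcatechol,8.83,0.02,13.93,0.05,,
4-Methylcatechol,9.36,0.01,13.49,0.06,,
4-Ethylcatechol,8.32,0.03,13.53,0.05,,
"3,4-Dihydroxydihydrocinnamic acid",4.86,0.07,6.97,0.02,11.75,0.01
"3,4-Dihydroxyphenylacetic acid",5.18,0.04,10.04,0.07,12.01,0.04
Catechol,8.83,0.03,13.07,0.05,,
Norepinephrine,8.63,0.06,10.60,0.08,12.94,0.03
"1,2,4-Benzenetriol",9.24,0.05,11.04,0.04,12.91,0.03
Caffeic acid,3.95,0.03,8.47,0.04,12.56,0.05
Dopamine,8.91,0.02,10.62,0.06,12.67,0.04
4-Chlorocatechol,7.90,0.02,10.35,0.03,,
Epinephrine,8.63,0.04,10.90,0.05,12.61,0.07
"3,4-Dihydroxybenzaldehyde",8.76,0.05,11.77,0.07,,
"3,4-Dihydroxybenzoic acid",3.17,0.09,9.10,0.08,11.77,0.05
"3,4-Dihydroxybenzylamine",5.67,0.08,8.85,0.06,12.50,0.04
"3,4-Dihydroxybenzonitrile",6.47,0.02,11.71,0.05,,
4-Nitrocatechol,5.93,0.05,11.05,0.04,,
Adrenalone,4.34,0.04,6.43,0.06,11.85,0.02
Dopa,2.06,0.06,8.55,0.06,9.93,0.03
Catechin,8.67,0.07,9.37,0.05,11.60,0.02
Quercetin,6.76,0.04,9.10,0.03,11.26,0.05
Chlorogenic acid,3.36,0.05,8.10,0.04,11.51,0.04
Isoprenaline,8.24,0.07,9.99,0.06,,
Nordihydroguaiaretic acid,9.38,0.04,,,,
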