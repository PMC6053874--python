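compound,experimental,PCM,IPCM,CPCM
Catechol,8.83,8.77,8.58,8.82
4-Nitrocatechol,5.93,5.58,5.13,6.10
4-Ethylcatechol,8.29,8.44,8.89,8.20
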