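istd_id,name,ms_mode,formula,mass_shift_Da
ISTD_Alanine,Alanine ISTD,LC,,3
ISTD_Arginine,Arginine ISTD,LC,,3
ISTD_Asparagine,Asparagine ISTD,LC,,3
ISTD_Aspartate,Aspartate ISTD,LC,,3
ISTD_Citrulline,Citrulline ISTD,LC,,3
ISTD_Glutamine,Glutamine ISTD,LC,,3
ISTD_Glutamate,Glutamate ISTD,LC,,3
ISTD_Glycine,Glycine ISTD,LC,,3
ISTD_Histidine,Histidine ISTD,LC,,3
ISTD_Isoleucine,Isoleucine ISTD,LC,,3
ISTD_Leucine,Leucine ISTD,LC,,3
ISTD_Lysine,Lysine ISTD,LC,,3
ISTD_Methionine,Methionine ISTD,LC,,3
ISTD_Ornithine,Ornithine ISTD,LC,,3
ISTD_Phenylalanine,Phenylalanine ISTD,LC,,3
ISTD_Proline,Proline ISTD,LC,,3
ISTD_Serine,Serine ISTD,LC,,3
ISTD_Threonine,Threonine ISTD,LC,,3
ISTD_Tryptophan,Tryptophan ISTD,LC,,3
ISTD_Tyrosine,Tyrosine ISTD,LC,,3
ISTD_Valine,Valine ISTD,LC,,3
ISTD_Taurine,Taurine ISTD,LC,,2
ISTD_Sarcosine,Sarcosine ISTD,LC,,3
ISTD_Acetyl_ornithine,Acetyl-ornithine ISTD,LC,,3
ISTD_ADMA,ADMA ISTD,LC,,3
ISTD_SDMA,SDMA ISTD,LC,,3
ISTD_total_DMA,total DMA ISTD,LC,,3
ISTD_alpha_AAA,alpha-AAA ISTD,LC,,3
ISTD_Carnosine,Carnosine ISTD,LC,,3
ISTD_Creatinine,Creatinine ISTD,LC,,3
ISTD_Histamine,Histamine ISTD,LC,,3
ISTD_Kynurenine,Kynurenine ISTD,LC,,3
ISTD_Methionine_sulfoxide,Methionine sulfoxide ISTD,LC,,3
ISTD_Nitrotyrosine,Nitrotyrosine ISTD,LC,,3
ISTD_trans_4_Hydroxyproline,trans-4-Hydroxyproline ISTD,LC,,3
ISTD_Phenylethylamine,Phenylethylamine ISTD,LC,,3
ISTD_Putrescine,Putrescine ISTD,LC,,3
ISTD_Serotonin,Serotonin ISTD,LC,,3
ISTD_Spermidine,Spermidine ISTD,LC,,3
ISTD_Spermine,Spermine ISTD,LC,,3
ISTD_DOPA,DOPA ISTD,LC,,3
ISTD_Dopamine,Dopamine ISTD,LC,,3
ISTD_AC_short,d3-C2 carnitine,FIA,,
ISTD_AC_medium,d3-C8 carnitine,FIA,,
ISTD_AC_long,d3-C16 carnitine,FIA,,
ISTD_AC_free,d9-C0 carnitine,FIA,,
ISTD_lysoPC,lysoPC a C18:0 (d4),FIA,,
ISTD_PCaa_low,PC aa C28:0 (d6),FIA,,
ISTD_PCaa_mid,PC aa C36:0 (d6),FIA,,
ISTD_PCaa_high,PC aa C42:0 (d6),FIA,,
ISTD_PCae_low,PC ae C30:0 (d6),FIA,,
ISTD_PCae_mid,PC ae C38:0 (d6),FIA,,
ISTD_PCae_high,PC ae C44:0 (d6),FIA,,
ISTD_SM_low,SM C16:0 (d3),FIA,,
ISTD_SM_high,SM C24:0 (d3),FIA,,
ISTD_H1,13C6-glucose,FIA,,
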