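tissue,f_ew,f_iw,f_nl,f_np,ap_mg_g,ra_albumin,provenance
adipose,0.135,0.017,0.790,0.0020,0.40,0.049,Rodgers & Rowland tissue-composition compilation
bone,0.100,0.346,0.074,0.0011,0.67,0.100,Rodgers & Rowland tissue-composition compilation
brain,0.162,0.620,0.051,0.0565,0.40,0.048,Rodgers & Rowland tissue-composition compilation
gut,0.282,0.475,0.0487,0.0163,2.41,0.158,Rodgers & Rowland tissue-composition compilation
heart,0.320,0.456,0.0115,0.0166,2.25,0.157,Rodgers & Rowland tissue-composition compilation
kidney,0.273,0.483,0.0207,0.0162,5.03,0.130,Rodgers & Rowland tissue-composition compilation
liver,0.161,0.573,0.0348,0.0252,4.56,0.086,Rodgers & Rowland tissue-composition compilation
lung,0.336,0.446,0.0220,0.0128,3.91,0.212,Rodgers & Rowland tissue-composition compilation
muscle,0.118,0.630,0.0238,0.0072,1.53,0.064,Rodgers & Rowland tissue-composition compilation
skin,0.382,0.291,0.0284,0.0111,1.32,0.277,Rodgers & Rowland tissue-composition compilation
spleen,0.207,0.579,0.0201,0.0198,3.18,0.097,Rodgers & Rowland tissue-composition compilation
pancreas,0.282,0.475,0.0487,0.0163,2.41,0.158,assigned: gut values as surrogate (not tabulated)
stomach,0.282,0.475,0.0487,0.0163,2.41,0.158,assigned: gut values as surrogate (not tabulated)
rest,0.118,0.630,0.0238,0.0072,1.53,0.064,assigned: muscle values as surrogate (lumped organ)
plasma,0.945,0.0,0.0023,0.0013,0.0,1.0,Rodgers & Rowland plasma lipid fractions
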