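sample_id,phenotype,m_value,m_se,c_half_observed,dg0,dg0_se,ddg_foldx,ddg_experiment
WT,health,1.7,0.1,3.0,-5.3,0.1,0.0,0.0
I738T,PAIS,1.3,0.1,2.2,-3.0,0.2,1.4,2.3
C807Y,PAIS,1.1,0.2,2.0,-2.2,0.1,6.2,3.1
W752R,CAIS,0.9,0.1,1.9,-1.7,0.3,3.6,3.6
L813F,CAIS,0.6,0.3,2.2,-1.5,0.1,6.3,3.8
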