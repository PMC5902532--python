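name,icd10,risk_per_10k_sv,q_min,fixed,k,q,l_rel,detriment
esophagus,C15,15,0.1,0,,,,
stomach,C16,79,0.1,0,,,,
colon,C18,65,0.1,0,,,,
liver,C22,30,0.1,0,,,,
lung,C34,114,0.1,0,,,,
bone,C40-C41,7,0.1,0,,,,
skin,C44,1000,0.0,0,,,,
breast,C50,112,0.1,0,,,,
ovary,C56,11,0.1,0,,,,
bladder,C67,43,0.1,0,,,,
thyroid,C73,33,0.2,0,,,,
bone_marrow,C91-C95,42,0.1,0,,,,
gonads,,20,0.1,1,0.80,0.82,1.32,25.4
remainder,,144,0.1,1,0.49,0.54,1.03,113.5
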