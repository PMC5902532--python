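name,k,q,l_rel,detriment
esophagus,0.94,0.95,0.95,14.2
stomach,0.46,0.51,0.89,51.7
colon,0.38,0.44,0.84,35.6
liver,0.75,0.78,0.96,27.2
lung,0.83,0.85,0.80,88.9
bone,0.44,0.50,2.1,10.6
skin,0.0023,0.0023,0.73,3.3
breast,0.16,0.24,1.03,41.7
ovary,0.62,0.66,0.93,8.9
bladder,0.21,0.29,0.64,12.1
thyroid,0.03,0.22,0.85,6.8
bone_marrow,0.49,0.54,0.95,30.5
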