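horse,limb,time,median_thickness_mm,volume_mm3,field_T,mri_score,clinical_score,normal
1,LF,0,3.59,10529.87,1.5,,,0
1,LF,2 W,3.55,10988.45,1.5,0,0,0
1,LF,3 M,3.15,9424.53,1.5,-1,-1,0
2,LF,0,2.09,5836.98,0.27,,,0
2,LF,4 M,1.69,5992.24,0.27,1,0,0
2,LF,10 M,4.37,6308.82,1.5,0,-1,0
2,RF,0,4.18,16125.06,0.27,,,0
2,RF,4 M,1.92,5616.88,0.27,-1,0,0
2,RF,10 M,4.24,16107.65,1.5,-1,-1,0
3,LF,0,5.24,13500.79,1.5,,,0
3,LF,7 M,4.36,10486.49,1.5,1,1,0
3,RF,0,4.82,16549.50,1.5,,,1
3,RF,7 M,4.34,16164.58,1.5,0,0,1
4,LF,0 M,3.78,12286.69,1.5,,,0
4,LF,10 M,3.58,12608.85,1.5,1,1,0
4,RF,0 M,3.91,13122.64,1.5,,,0
4,RF,10 M,3.67,12655.33,1.5,-1,1,0
5,LF,0 M,3.74,10784.55,0.27,,,0
5,LF,5 M,2.21,5953.20,0.27,0,0,0
5,RF,0 M,2.32,6101.07,0.27,,,0
5,RF,5 M,2.55,8487.66,0.27,0,0,0
6,RF,0 M,4.30,11582.57,1.5,,,0
6,RF,2 M,3.78,10596.44,1.5,1,1,0
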