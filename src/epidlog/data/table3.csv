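site,beam,mu,gpr_prop,gpr_mach,sas,mcsv,lt,ltmcs,aav,lsv,mlc_mn,mlc_sn,mlc_mx,mlc_sx,mu_mean,mu_std
Bone,6,1639,95.2,98.7,2.837,0.021,56.483,0.015,0.030,0.700,4.845,5.405,17.681,9.741,9.269,36.021
Brain,6,734,95.3,99.2,1.520,0.018,101.350,0.009,0.022,0.824,4.830,1.568,12.408,0.928,1.420,0.946
Breast,6,923,95.2,96.1,1.513,0.015,52.295,0.011,0.018,0.839,4.677,2.328,13.022,6.324,4.690,22.721
Breast,6,1366,93.9,94.5,1.583,0.016,53.823,0.012,0.018,0.859,5.025,3.029,13.008,7.544,12.074,90.754
Breast,6,1816,91.3,88.3,1.571,0.012,46.817,0.009,0.014,0.829,4.383,2.337,13.033,7.246,9.652,57.890
Breast,6,1840,88.9,93.3,1.614,0.013,61.378,0.009,0.016,0.836,6.377,2.250,12.359,1.139,7.694,8.004
Breast,6,1865,93.2,93.5,1.591,0.013,54.856,0.010,0.016,0.863,4.866,2.521,13.063,6.843,9.923,58.840
Lung,6,558,99.4,99.9,2.220,0.029,34.979,0.024,0.037,0.783,2.329,2.535,15.111,8.237,1.603,1.336
Lung,6,769,99.0,99.4,2.007,0.042,37.011,0.035,0.056,0.756,6.015,3.287,32.091,10.532,5.849,4.719
Pancreas,6,1889,99.2,99.9,2.173,0.021,68.965,0.014,0.029,0.731,4.051,2.851,17.876,6.005,5.309,3.375
Pelvic seed,6,1971,97.3,98.6,1.976,0.010,117.596,0.004,0.014,0.773,8.031,6.759,25.721,15.873,7.077,43.733
PNS,6,582,93.0,97.9,1.699,0.024,27.433,0.021,0.030,0.802,6.359,4.066,18.509,13.487,13.313,98.461
Liver,6 FFF,2086,93.8,99.4,1.709,0.020,80.769,0.012,0.023,0.846,4.143,2.179,20.620,2.141,5.853,7.093
Lung,6 FFF,2281,97.6,99.8,1.629,0.013,73.848,0.008,0.016,0.822,5.522,4.537,24.517,9.990,6.079,7.946
Lung,6 FFF,1198,98.6,99.9,2.819,0.041,41.279,0.033,0.057,0.720,2.568,3.077,13.909,7.294,6.537,10.363
Lung,6 FFF,2078,86.3,99.6,1.585,0.018,69.551,0.012,0.021,0.843,8.269,4.695,24.778,13.278,20.507,55.211
Lung,6 FFF,1855,99.5,100.0,2.473,0.032,54.840,0.023,0.045,0.710,3.699,3.888,16.581,6.126,5.213,6.570
Ovary,6 FFF,871,97.1,99.2,3.221,0.014,52.275,0.010,0.021,0.660,4.262,4.586,9.930,6.692,2.479,2.438
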