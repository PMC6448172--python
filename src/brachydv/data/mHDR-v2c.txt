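# Schematic TG-43 source description, mHDR-v2c-style Ir-192 HDR source.
# SYNTHETIC: consensus-style average of the schematic v2 and v2r tables.
[meta]
model_id mHDR-v2c
active_length_mm 3.5
lambda_cGy_per_hU 1.1088
half_life_days 73.83

[radial]
# r_cm  g
0.25  0.991
0.50  0.996
1.00  1.000
1.50  1.000
2.00  0.997
3.00  0.986
4.00  0.970
5.00  0.948
6.00  0.925
8.00  0.867
10.00 0.804

[anisotropy]
r\theta 0 10 20 30 45 60 75 90 105 120 135 150 170 180
0.25  0.678 0.758 0.849 0.909 0.960 0.984 0.996 1.000 0.996 0.984 0.958 0.904 0.738 0.648
0.50  0.688 0.768 0.857 0.914 0.962 0.986 0.997 1.000 0.997 0.986 0.960 0.909 0.750 0.660
1.00  0.698 0.778 0.864 0.919 0.964 0.987 0.997 1.000 0.997 0.987 0.962 0.914 0.760 0.670
2.00  0.713 0.790 0.871 0.925 0.967 0.989 0.998 1.000 0.998 0.989 0.966 0.919 0.772 0.684
5.00  0.738 0.808 0.883 0.932 0.971 0.990 0.998 1.000 0.998 0.990 0.970 0.927 0.790 0.708
10.00 0.766 0.828 0.895 0.939 0.975 0.991 0.998 1.000 0.998 0.991 0.973 0.934 0.808 0.733
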