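# Schematic TG-43 source description, mHDR-v2-style Ir-192 HDR source.
# SYNTHETIC: coarse illustrative tables satisfying g(1 cm) = 1 and
# F(r, 90 deg) = 1; replace with published consensus data for clinical use.
[meta]
model_id mHDR-v2
active_length_mm 3.5
lambda_cGy_per_hU 1.109
half_life_days 73.83

[radial]
# r_cm  g
0.25  0.990
0.50  0.996
1.00  1.000
1.50  1.000
2.00  0.997
3.00  0.986
4.00  0.970
5.00  0.949
6.00  0.925
8.00  0.868
10.00 0.805

[anisotropy]
# first row: theta grid (deg); first column: r grid (cm); body: F(r, theta)
r\theta 0 10 20 30 45 60 75 90 105 120 135 150 170 180
0.25  0.680 0.760 0.850 0.910 0.960 0.985 0.996 1.000 0.996 0.985 0.958 0.905 0.740 0.650
0.50  0.690 0.770 0.858 0.915 0.962 0.986 0.997 1.000 0.997 0.986 0.960 0.910 0.752 0.662
1.00  0.700 0.780 0.865 0.920 0.965 0.988 0.997 1.000 0.997 0.988 0.963 0.915 0.762 0.672
2.00  0.715 0.792 0.872 0.926 0.968 0.989 0.998 1.000 0.998 0.989 0.966 0.920 0.774 0.686
5.00  0.740 0.810 0.884 0.933 0.972 0.990 0.998 1.000 0.998 0.990 0.970 0.928 0.792 0.710
10.00 0.768 0.830 0.896 0.940 0.975 0.991 0.998 1.000 0.998 0.991 0.974 0.935 0.810 0.735
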