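# Schematic TG-43 source description, mHDR-v2r-style Ir-192 HDR source.
# SYNTHETIC: a sub-percent perturbation of the mHDR-v2 schematic tables,
# mirroring the small revision between the two published datasets.
[meta]
model_id mHDR-v2r
active_length_mm 3.6
lambda_cGy_per_hU 1.1085
half_life_days 73.83

[radial]
# r_cm  g
0.25  0.992
0.50  0.997
1.00  1.000
1.50  1.000
2.00  0.996
3.00  0.985
4.00  0.969
5.00  0.948
6.00  0.924
8.00  0.866
10.00 0.803

[anisotropy]
r\theta 0 10 20 30 45 60 75 90 105 120 135 150 170 180
0.25  0.676 0.757 0.848 0.908 0.959 0.984 0.996 1.000 0.996 0.984 0.957 0.903 0.737 0.646
0.50  0.686 0.767 0.856 0.913 0.961 0.985 0.997 1.000 0.997 0.985 0.959 0.908 0.749 0.658
1.00  0.697 0.777 0.863 0.918 0.964 0.987 0.997 1.000 0.997 0.987 0.962 0.913 0.759 0.669
2.00  0.712 0.789 0.870 0.924 0.967 0.988 0.998 1.000 0.998 0.988 0.965 0.918 0.771 0.683
5.00  0.737 0.807 0.882 0.931 0.971 0.989 0.998 1.000 0.998 0.989 0.969 0.926 0.789 0.707
10.00 0.765 0.827 0.894 0.938 0.974 0.990 0.998 1.000 0.998 0.990 0.973 0.933 0.807 0.732
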