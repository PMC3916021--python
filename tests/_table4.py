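"""Published two-testing-set benchmark table: per algorithm, the confusion
counts (TP, FN, TN, FP) and the reported SN/SP/ACC/MCC at 3 decimals."""

# (cohort, algorithm, tp, fn, tn, fp, sn, sp, acc, mcc)
TABLE4_ROWS = [
    ("Desmedt", "GGI", 84, 45, 29, 32, 0.651, 0.475, 0.595, 0.121),
    ("Desmedt", "70g", 53, 76, 27, 34, 0.411, 0.443, 0.421, -0.137),
    ("Desmedt", "76g", 78, 51, 23, 38, 0.605, 0.377, 0.532, -0.018),
    ("Desmedt", "ITI", 95, 34, 33, 28, 0.736, 0.541, 0.674, 0.271),
    ("Desmedt", "HRGE", 115, 14, 36, 25, 0.891, 0.590, 0.795, 0.511),
    ("Desmedt", "RRHGE-H", 103, 26, 46, 15, 0.798, 0.754, 0.784, 0.532),
    ("Desmedt", "RRHGE-HI", 100, 29, 48, 13, 0.775, 0.787, 0.779, 0.535),
    ("Desmedt", "RRHGE-TSN", 119, 10, 54, 7, 0.922, 0.885, 0.911, 0.798),
    ("Desmedt", "RRHGE", 123, 6, 56, 5, 0.953, 0.918, 0.942, 0.868),
    ("vandeVijver", "GGI", 77, 37, 17, 19, 0.675, 0.472, 0.627, 0.131),
    ("vandeVijver", "70g", 71, 43, 19, 17, 0.623, 0.528, 0.600, 0.131),
    ("vandeVijver", "76g", 72, 42, 20, 16, 0.632, 0.556, 0.613, 0.162),
    ("vandeVijver", "ITI", 59, 55, 19, 17, 0.518, 0.528, 0.520, 0.039),
    ("vandeVijver", "HRGE", 70, 44, 20, 16, 0.614, 0.556, 0.600, 0.146),
    ("vandeVijver", "RRHGE-H", 92, 22, 14, 18, 0.807, 0.438, 0.726, 0.235),
    ("vandeVijver", "RRHGE-HI", 94, 20, 22, 14, 0.825, 0.611, 0.773, 0.414),
    ("vandeVijver", "RRHGE-TSN", 101, 13, 26, 10, 0.886, 0.722, 0.847, 0.592),
    ("vandeVijver", "RRHGE", 105, 9, 28, 8, 0.921, 0.778, 0.887, 0.692),
]
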