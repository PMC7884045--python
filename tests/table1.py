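"""Published top-30 CpG summary statistics used as worked-example inputs.

Columns: probe id, GCC p-value, kinship p-value, combined (min) p-value,
and the FDR value adjusted against the full test count M_TOTAL = 427,409.
"""

M_TOTAL = 427_409

# probe_id, p_gcc, p_kin, p_combined, fdr
TOP30 = [
    ("cg08734237", 8.3871e-07, 0.0002, 8.3871e-07, 0.2174),
    ("cg17916473", 1.0173e-06, 0.2816, 1.0173e-06, 0.2174),
    ("cg23988749", 0.2832, 2.5999e-06, 2.5999e-06, 0.2716),
    ("cg08594651", 2.7554e-06, 0.1284, 2.7554e-06, 0.2716),
    ("cg04817034", 3.9680e-06, 0.3502, 3.9680e-06, 0.2716),
    ("cg16662451", 0.1238, 5.6459e-06, 5.6459e-06, 0.2716),
    ("cg15322207", 6.0941e-06, 0.9221, 6.0941e-06, 0.2716),
    ("cg13541769", 6.7241e-06, 0.0176, 6.7241e-06, 0.2716),
    ("cg23731089", 6.7682e-06, 0.0999, 6.7682e-06, 0.2716),
    ("cg18147395", 6.8905e-06, 0.2675, 6.8905e-06, 0.2716),
    ("cg11465226", 6.9891e-06, 0.2582, 6.9891e-06, 0.2716),
    ("cg26963367", 7.6279e-06, 0.1994, 7.6279e-06, 0.2717),
    ("cg04465201", 8.5029e-06, 0.0009, 8.5029e-06, 0.2759),
    ("cg20497212", 9.0372e-06, 0.3105, 9.0372e-06, 0.2759),
    ("cg20482334", 0.2305, 1.3245e-05, 1.3245e-05, 0.2832),
    ("cg00744656", 1.3310e-05, 0.8899, 1.3310e-05, 0.2832),
    ("cg01273125", 1.9438e-05, 0.3767, 1.9438e-05, 0.2832),
    ("cg20644253", 0.0162, 2.1548e-05, 2.1548e-05, 0.2832),
    ("cg18191418", 2.2055e-05, 0.0348, 2.2055e-05, 0.2832),
    ("cg01182076", 0.2832, 2.2968e-05, 2.2968e-05, 0.2832),
    ("cg16126079", 2.6257e-05, 0.5574, 2.6257e-05, 0.2832),
    ("cg14100184", 0.0803, 2.6325e-05, 2.6325e-05, 0.2832),
    ("cg10238145", 2.7406e-05, 0.8040, 2.7406e-05, 0.2832),
    ("cg07683636", 2.8700e-05, 0.1317, 2.8700e-05, 0.2832),
    ("cg00848394", 0.0898, 3.0661e-05, 3.0661e-05, 0.2832),
    ("cg07537095", 3.1549e-05, 0.7694, 3.1549e-05, 0.2832),
    ("cg14994060", 0.2627, 3.1938e-05, 3.1938e-05, 0.2832),
    ("cg04941278", 0.2523, 3.2285e-05, 3.2285e-05, 0.2832),
    ("cg09190408", 3.3643e-05, 0.0316, 3.3643e-05, 0.2832),
    ("cg21112485", 0.0011, 3.5209e-05, 3.5209e-05, 0.2832),
]

PROBE_IDS = [r[0] for r in TOP30]
P_GCC = [r[1] for r in TOP30]
P_KIN = [r[2] for r in TOP30]
P_COMBINED = [r[3] for r in TOP30]
FDR = [r[4] for r in TOP30]
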