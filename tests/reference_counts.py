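"""Published per-model retrieval counts from a seven-target screening study.

Each row is one linear QSAR model (three descriptor-set sizes per target,
21 models per method); the values are the number of active compounds
retrieved within the top L places on each compound set.  Used as fixed
input for the cross-set consistency regressions.
"""

# MLR models: (train, validation) actives-in-top-L counts
MLR_TRAIN = [48, 48, 48, 47, 48, 49, 43, 44, 45, 67, 69, 71, 74, 74, 75, 57, 57, 58, 53, 53, 54]
MLR_VALID = [43, 45, 42, 42, 39, 41, 32, 34, 30, 64, 68, 72, 68, 67, 70, 56, 57, 56, 56, 55, 53]

# Enrichment-optimized models: train, validation and first test-pool counts
EOA_TRAIN = [47, 47, 47, 48, 49, 48, 45, 45, 47, 67, 75, 77, 74, 74, 74, 56, 57, 57, 49, 49, 56]
EOA_VALID = [40, 44, 42, 37, 42, 38, 34, 32, 33, 60, 61, 59, 65, 67, 70, 54, 55, 54, 47, 45, 52]
EOA_TEST1 = [40, 39, 38, 31, 32, 32, 0, 1, 0, 86, 89, 87, 49, 0, 57, 29, 20, 41, 25, 25, 15]

# index of the single outlying model (one target's mid-sized descriptor set)
# whose removal restores the train/test correlation
EOA_TEST1_OUTLIER_INDEX = 13
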