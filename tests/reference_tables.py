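"""Published per-combination confusion matrices of the banana grading
study, used as metric-recomputation fixtures: counts (rows = true stage
MS1..MS4, columns = predicted), the printed per-class recall rates and
the printed overall accuracy."""

REFERENCE_CONFUSIONS = {
    ("color", "nb"): {
        "counts": [[36, 0, 0, 0], [0, 29, 0, 0], [0, 1, 28, 0], [0, 0, 0, 27]],
        "rr": [100.0, 100.0, 96.6, 100.0],
        "oa": 99.2,
    },
    ("color", "lda"): {
        "counts": [[36, 0, 0, 0], [0, 29, 0, 0], [0, 0, 29, 0], [0, 0, 0, 27]],
        "rr": [100.0, 100.0, 100.0, 100.0],
        "oa": 100.0,
    },
    ("color", "svm"): {
        "counts": [[36, 0, 0, 0], [0, 28, 1, 0], [0, 0, 29, 0], [0, 0, 0, 27]],
        "rr": [100.0, 96.6, 100.0, 100.0],
        "oa": 99.2,
    },
    ("texture", "nb"): {
        "counts": [[35, 0, 1, 0], [0, 25, 4, 0], [1, 3, 25, 0], [0, 0, 0, 27]],
        "rr": [97.2, 86.2, 86.2, 100.0],
        "oa": 92.6,
    },
    ("texture", "lda"): {
        "counts": [[34, 0, 2, 0], [0, 23, 6, 0], [4, 4, 21, 0], [0, 0, 0, 27]],
        "rr": [94.4, 79.3, 72.4, 100.0],
        "oa": 86.8,
    },
    ("texture", "svm"): {
        "counts": [[35, 0, 1, 0], [0, 27, 2, 0], [2, 3, 24, 0], [0, 0, 0, 27]],
        "rr": [97.2, 93.1, 82.8, 100.0],
        "oa": 93.4,
    },
    ("shape", "nb"): {
        "counts": [[31, 1, 4, 0], [1, 23, 3, 2], [2, 4, 21, 2], [0, 0, 0, 27]],
        "rr": [86.1, 79.3, 72.4, 100.0],
        "oa": 84.3,
    },
    ("shape", "lda"): {
        "counts": [[27, 0, 9, 0], [1, 22, 5, 1], [1, 3, 25, 0], [0, 0, 0, 27]],
        "rr": [75.0, 75.9, 86.2, 100.0],
        "oa": 83.5,
    },
    ("shape", "svm"): {
        "counts": [[26, 1, 9, 0], [0, 24, 5, 0], [3, 3, 23, 0], [0, 0, 0, 27]],
        "rr": [72.2, 82.8, 79.3, 100.0],
        "oa": 82.6,
    },
}
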