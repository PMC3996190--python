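"""Published confusion-count tables used as worked examples of the metric
arithmetic.

The clinical evaluation this pipeline's conventions follow reported, for each
intraretinal layer, eye-level TP/FN/TN/FP counts together with PPV,
sensitivity and specificity rounded to two decimals, at both eye and scan
level (scan counts are six times the eye counts).  The underlying patient
data are not public, so these tables cannot be regenerated from data; they
serve as fixed worked examples that the metric computations must reproduce
exactly from the printed counts.

Counts are stored at eye level only.  (One published scan-level cell, the
ONL+IS true negatives of the DM-vs-MDR table, prints 162 scans against 26
eyes; 26 eyes imply 156 scans and 26 is the count consistent with the printed
specificity and the group size, so the eye count is taken as authoritative.)
"""

from __future__ import annotations

from .enums import LayerName
from .protocol import ConfusionCounts, confusion_metrics

L = LayerName

#: table -> layer -> dict(tp, fn, tn, fp, ppv, sensitivity, specificity)
REFERENCE_TABLES: dict[str, dict[LayerName, dict]] = {
    # Test 1 (healthy vs MDR), TH -> FD
    "test1_th_fd": {
        L.RNFL: dict(tp=48, fn=6, tn=10, fp=33, ppv=0.59, sensitivity=0.89, specificity=0.23),
        L.GCL_IPL: dict(tp=49, fn=5, tn=35, fp=8, ppv=0.86, sensitivity=0.91, specificity=0.81),
        L.INL: dict(tp=48, fn=6, tn=23, fp=20, ppv=0.71, sensitivity=0.89, specificity=0.53),
        L.OPL: dict(tp=48, fn=6, tn=36, fp=7, ppv=0.87, sensitivity=0.89, specificity=0.84),
        L.ONL_IS: dict(tp=48, fn=6, tn=10, fp=33, ppv=0.59, sensitivity=0.89, specificity=0.23),
        L.OS: dict(tp=50, fn=4, tn=9, fp=34, ppv=0.60, sensitivity=0.93, specificity=0.21),
        L.RPE: dict(tp=51, fn=3, tn=11, fp=32, ppv=0.61, sensitivity=0.94, specificity=0.26),
    },
    # Test 1 (healthy vs MDR), TR -> FD
    "test1_tr_fd": {
        L.RNFL: dict(tp=48, fn=6, tn=10, fp=33, ppv=0.59, sensitivity=0.89, specificity=0.23),
        L.GCL_IPL: dict(tp=49, fn=5, tn=35, fp=8, ppv=0.86, sensitivity=0.91, specificity=0.81),
        L.INL: dict(tp=48, fn=6, tn=23, fp=20, ppv=0.71, sensitivity=0.89, specificity=0.53),
        L.OPL: dict(tp=48, fn=6, tn=37, fp=6, ppv=0.89, sensitivity=0.89, specificity=0.86),
        L.ONL_IS: dict(tp=48, fn=6, tn=9, fp=34, ppv=0.59, sensitivity=0.89, specificity=0.21),
        L.OS: dict(tp=50, fn=4, tn=9, fp=34, ppv=0.60, sensitivity=0.93, specificity=0.21),
        L.RPE: dict(tp=51, fn=3, tn=11, fp=32, ppv=0.61, sensitivity=0.94, specificity=0.26),
    },
    # Test 2 (training-set size sweep), TH -> FD; keys <layer>_<n_train>
    "test2_th_fd": {
        (L.GCL_IPL, 20): dict(tp=49, fn=5, tn=35, fp=8, ppv=0.86, sensitivity=0.91, specificity=0.81),
        (L.OPL, 20): dict(tp=48, fn=6, tn=36, fp=7, ppv=0.87, sensitivity=0.89, specificity=0.84),
        (L.GCL_IPL, 30): dict(tp=39, fn=5, tn=35, fp=8, ppv=0.83, sensitivity=0.89, specificity=0.81),
        (L.OPL, 30): dict(tp=39, fn=5, tn=36, fp=7, ppv=0.85, sensitivity=0.89, specificity=0.84),
        (L.GCL_IPL, 40): dict(tp=29, fn=5, tn=35, fp=8, ppv=0.78, sensitivity=0.85, specificity=0.81),
        (L.OPL, 40): dict(tp=29, fn=5, tn=36, fp=7, ppv=0.81, sensitivity=0.85, specificity=0.84),
    },
    # Test 2, TR -> FD
    "test2_tr_fd": {
        (L.GCL_IPL, 20): dict(tp=49, fn=5, tn=35, fp=8, ppv=0.86, sensitivity=0.91, specificity=0.81),
        (L.OPL, 20): dict(tp=48, fn=6, tn=37, fp=6, ppv=0.89, sensitivity=0.89, specificity=0.86),
        (L.GCL_IPL, 30): dict(tp=39, fn=5, tn=35, fp=8, ppv=0.83, sensitivity=0.89, specificity=0.81),
        (L.OPL, 30): dict(tp=39, fn=5, tn=36, fp=7, ppv=0.85, sensitivity=0.89, specificity=0.84),
        (L.GCL_IPL, 40): dict(tp=29, fn=5, tn=35, fp=8, ppv=0.78, sensitivity=0.85, specificity=0.81),
        (L.OPL, 40): dict(tp=29, fn=5, tn=37, fp=6, ppv=0.83, sensitivity=0.85, specificity=0.86),
    },
    # Test 3 (DM vs MDR), TH -> FD
    "test3_th_fd": {
        L.RNFL: dict(tp=18, fn=5, tn=30, fp=8, ppv=0.69, sensitivity=0.78, specificity=0.79),
        L.GCL_IPL: dict(tp=18, fn=5, tn=26, fp=12, ppv=0.60, sensitivity=0.78, specificity=0.68),
        L.INL: dict(tp=15, fn=8, tn=32, fp=6, ppv=0.71, sensitivity=0.65, specificity=0.84),
        L.OPL: dict(tp=4, fn=19, tn=28, fp=10, ppv=0.29, sensitivity=0.17, specificity=0.74),
        L.ONL_IS: dict(tp=10, fn=13, tn=26, fp=12, ppv=0.45, sensitivity=0.43, specificity=0.68),
        L.OS: dict(tp=18, fn=5, tn=31, fp=7, ppv=0.72, sensitivity=0.78, specificity=0.82),
        L.RPE: dict(tp=20, fn=3, tn=33, fp=5, ppv=0.80, sensitivity=0.87, specificity=0.87),
    },
}


def reproduce_worked_examples() -> list[dict]:
    """Recompute PPV/sensitivity/specificity from every stored count set.

    Returns one record per table column with the recomputed metrics (2-dp
    rounded), the printed metrics, and whether they agree.
    """
    results = []
    for table, columns in REFERENCE_TABLES.items():
        for key, ref in columns.items():
            layer, n_train = key if isinstance(key, tuple) else (key, None)
            counts = ConfusionCounts(
                tp=ref["tp"], fn=ref["fn"], tn=ref["tn"], fp=ref["fp"]
            )
            m = confusion_metrics(counts)
            computed = {
                "ppv": round(m["ppv"], 2),
                "sensitivity": round(m["sensitivity"], 2),
                "specificity": round(m["specificity"], 2),
            }
            printed = {k: ref[k] for k in ("ppv", "sensitivity", "specificity")}
            results.append(
                {
                    "table": table,
                    "layer": layer.value,
                    "n_train": n_train,
                    "counts": counts.to_dict(),
                    "computed": computed,
                    "printed": printed,
                    "match": computed == printed,
                }
            )
    return results
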