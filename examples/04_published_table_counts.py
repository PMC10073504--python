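"""Reproduce the selection bookkeeping of the published marker table.

The shipped table records, for each of the 39 features and both statistical
methods, whether it was significant ("*"), significant but discarded as
redundant ("*(—)"), or not significant ("—").  The tally recovers every
printed count: M1 selects 33 features preliminarily, discards 11 and keeps
22; M3 selects 17, discards 4 and keeps 13 (5 ECG + 4 BVP + 4 GSR).
"""

from transfeat.selection import AnnotationTable, selection_from_annotations

table = AnnotationTable.bundled()
for method in ("M1", "M3"):
    out = selection_from_annotations(table, method)
    print(f"{method}: preliminary {out['preliminary_count']}, "
          f"discarded {out['discarded_count']}, final {out['final_count']} "
          f"(per signal {out['per_signal_final']})")
    print("   final features:", ", ".join(out["final_features"]))
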