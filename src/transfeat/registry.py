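"""Canonical registry of the 39 physiological features.

The feature set spans three peripheral signals: 15 ECG (heart rate
variability) features, 12 BVP (pulse rate variability and pulse-wave
amplitude) features and 12 GSR (electrodermal activity) features.  The
registry order is the canonical tie-break order used by the greedy
redundancy filter in :mod:`transfeat.selection`.
"""

from __future__ import annotations

ECG_FEATURES: tuple[str, ...] = (
    "MEANRR", "SDNN", "RMSSD", "NN50", "PNN50", "HR",
    "VLF", "LF", "HF", "LF_HF",
    "MSE1", "MSE2", "MSE3", "MSE4", "MSE5",
)

BVP_FEATURES: tuple[str, ...] = (
    "PR", "SDNN", "RMSSD", "MEANRR", "LF", "HF",
    "WIDTH", "H_W", "MAXPA", "STDPA", "MEANPA", "HIGH",
)

GSR_FEATURES: tuple[str, ...] = (
    "MEANT", "STDT", "AUCT", "STDR", "AUCR", "NUMP",
    "MAXPA", "MEANPA", "STDPA", "MEANPR", "STDPR", "PSD",
)

SIGNALS: tuple[str, ...] = ("ECG", "BVP", "GSR")

#: Column names of the feature matrix, e.g. ``"SDNN_ECG"``.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{name}_{sig}"
    for sig, names in (("ECG", ECG_FEATURES), ("BVP", BVP_FEATURES), ("GSR", GSR_FEATURES))
    for name in names
)

assert len(FEATURE_COLUMNS) == 39 and len(set(FEATURE_COLUMNS)) == 39

#: Alternative spellings accepted on input (reports always use canonical names).
ALIASES: dict[str, str] = {
    "LF/HF_ECG": "LF_HF_ECG",
    "AUCP_GSR": "AUCR_GSR",
}


def canonical_name(name: str) -> str:
    """Resolve an alias (``LF/HF_ECG``, ``AUCP_GSR``) to its canonical column name."""
    name = name.strip()
    return ALIASES.get(name, name)


def signal_group(column: str) -> str:
    """Return the signal group (``ECG``/``BVP``/``GSR``) of a feature column."""
    sig = canonical_name(column).rsplit("_", 1)[-1]
    if sig not in SIGNALS:
        raise ValueError(f"cannot infer signal group of feature {column!r}")
    return sig


def group_columns(signal: str) -> list[str]:
    """All feature columns belonging to one signal group."""
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}")
    return [c for c in FEATURE_COLUMNS if c.endswith("_" + signal)]
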