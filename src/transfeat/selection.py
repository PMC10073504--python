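"""Feature selection: discrete-state (M1), PCA (M2) and transition-based (M3).

M1 tests each feature between discrete emotional states (Kruskal-Wallis on
per-subject segment means, all pairwise comparisons significant), then
drops features correlated above |r| = 0.9 with an already-kept feature.

M2 reduces each signal group to a fixed number of principal components.

M3 — the transition method — tests each feature *across emotional state
transitions*: per subject, the feature's mean over the segment before a
transition is paired with its mean after; a Shapiro-Wilk gate routes each
transition's paired differences to a paired t-test (normal) or a Wilcoxon
signed-rank test (otherwise).  A feature is preliminarily selected when it
is significant in every transition of the design, and the same greedy
redundancy filter follows.  Relax blocks act as the neutral flank of a
transition, so under the default protocol all three transitions pair
immediately adjacent segments.

The annotation utilities reproduce published selection bookkeeping from a
marker table ("*" significant, "*(—)" significant but redundancy-discarded,
"—" not significant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from . import registry

DISCRETE_PAIRS = (("neutral", "negative"), ("negative", "positive"), ("positive", "neutral"))
TRANSITION_PAIRS = (("neutral", "negative"), ("negative", "neutral"), ("neutral", "positive"))

MARKERS = ("*", "*(—)", "—")


@dataclass
class ComparisonDesign:
    """Which state pairs (discrete) or transitions (before, after) to test."""

    mode: str = "transition"   # "discrete" | "transition"
    pairs: tuple[tuple[str, str], ...] = TRANSITION_PAIRS

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "transition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.pairs:
            raise ValueError("need at least one comparison pair")

    @classmethod
    def discrete_default(cls) -> "ComparisonDesign":
        return cls("discrete", DISCRETE_PAIRS)

    @classmethod
    def transition_default(cls) -> "ComparisonDesign":
        return cls("transition", TRANSITION_PAIRS)


@dataclass
class FeatureDecision:
    """Per-feature outcome of one selection run."""

    feature: str
    p_values: dict[str, float] = field(default_factory=dict)
    tests: dict[str, str] = field(default_factory=dict)
    significant: bool = False
    discarded_redundant: bool = False
    partner: str | None = None
    correlation: float | None = None
    constant: bool = False


@dataclass
class SelectionResult:
    """Outcome of a selection method on one feature matrix."""

    method: str
    alpha: float
    decisions: dict[str, FeatureDecision]
    final_subset: list[str]

    @property
    def significant_features(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d.significant]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "final_subset": self.final_subset,
            "features": {
                f: {
                    "p_values": d.p_values,
                    "tests": d.tests,
                    "significant": d.significant,
                    "discarded_redundant": d.discarded_redundant,
                    "partner": d.partner,
                    "correlation": d.correlation,
                }
                for f, d in self.decisions.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def segment_means(fm: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-(subject, segment) mean of each feature over its windows."""
    features = features or list(registry.FEATURE_COLUMNS)
    cols = [c for c in features if c in fm.columns]
    out = (fm.groupby(["subject", "segment", "label"], as_index=False)[cols]
             .mean())
    return out


def _transition_segments(fm: pd.DataFrame, pair: tuple[str, str],
                         relax_as: str = "neutral",
                         match: str = "first") -> list[tuple[int, int]]:
    """Segment-index pairs (before, after) realising one transition.

    Labels are mapped through the relax alias; each adjacency whose mapped
    labels equal the pair qualifies.  ``match`` = 'first' (default) or 'all'.
    """
    segs = (fm[["segment", "label"]].drop_duplicates()
            .sort_values("segment").to_records(index=False))
    mapped = [(int(s), relax_as if lb == "relax" else lb) for s, lb in segs]
    hits = [(mapped[i][0], mapped[i + 1][0])
            for i in range(len(mapped) - 1)
            if (mapped[i][1], mapped[i + 1][1]) == pair]
    if not hits:
        raise ValueError(f"transition {pair[0]}->{pair[1]} not present in timeline")
    return hits[:1] if match == "first" else hits


def paired_samples(fm: pd.DataFrame, pair: tuple[str, str],
                   features: list[str] | None = None,
                   relax_as: str = "neutral",
                   match: str = "first") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject (before, after) segment means flanking one transition.

    Returns two DataFrames indexed by subject with one column per feature.
    Subjects missing either flank are dropped.
    """
    features = features or [c for c in registry.FEATURE_COLUMNS if c in fm.columns]
    sm = segment_means(fm, features).set_index(["subject", "segment"])
    pairs_idx = _transition_segments(fm, pair, relax_as, match)
    befores, afters = [], []
    for b, a in pairs_idx:
        bdf = sm.xs(b, level="segment")[features]
        adf = sm.xs(a, level="segment")[features]
        common = bdf.index.intersection(adf.index)
        befores.append(bdf.loc[common])
        afters.append(adf.loc[common])
    before = pd.concat(befores).groupby(level=0).mean()
    after = pd.concat(afters).groupby(level=0).mean()
    return before, after


def _paired_test(diffs: np.ndarray, alpha_normality: float = 0.05) -> tuple[float, str]:
    """Shapiro-Wilk-gated paired test on the differences.

    Normal differences -> paired t-test; otherwise Wilcoxon signed rank
    (zeros discarded; exact null for n < 25, normal approximation with
    continuity correction otherwise).  Zero-variance differences give p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 3 or np.std(diffs) == 0:
        return 1.0, "degenerate"
    sw_p = stats.shapiro(diffs).pvalue
    if sw_p > alpha_normality:
        p = float(stats.ttest_rel(diffs, np.zeros_like(diffs)).pvalue)
        return p, "paired_t"
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0, "degenerate"
    method = "exact" if nonzero.size < 25 else "approx"
    p = float(stats.wilcoxon(diffs, zero_method="wilcox", correction=True,
                             method=method).pvalue)
    return p, "wilcoxon_signed_rank"


def transition_select(fm: pd.DataFrame,
                      design: ComparisonDesign | None = None,
                      alpha: float = 0.05,
                      features: list[str] | None = None,
                      relax_as: str = "neutral",
                      redundancy_threshold: float = 0.9,
                      apply_redundancy: bool = True) -> SelectionResult:
    """Transition-based selection (M3, stage 1 + redundancy stage).

    A feature is preliminarily selected iff its paired before/after test is
    significant at ``alpha`` in every transition of the design.
    """
    design = design or ComparisonDesign.transition_default()
    if design.mode != "transition":
        raise ValueError("transition_select needs a transition design")
    if fm["subject"].nunique() < 6:
        raise ValueError("need at least 6 subjects")
    features = features or [c for c in registry.FEATURE_COLUMNS if c in fm.columns]
    flanks = {pair: paired_samples(fm, pair, features, relax_as) for pair in design.pairs}
    decisions: dict[str, FeatureDecision] = {}
    for feat in features:
        d = FeatureDecision(feat)
        sig = True
        for pair in design.pairs:
            before, after = flanks[pair]
            diffs = (after[feat] - before[feat]).to_numpy()
            p, test = _paired_test(diffs)
            key = f"{pair[0]}->{pair[1]}"
            d.p_values[key] = p
            d.tests[key] = test
            sig = sig and (p < alpha)
        d.significant = sig
        decisions[feat] = d
    result = SelectionResult("M3", alpha, decisions,
                             [f for f in features if decisions[f].significant])
    if apply_redundancy:
        redundancy_filter(result, fm, threshold=redundancy_threshold)
    return result


def discrete_select(fm: pd.DataFrame,
                    design: ComparisonDesign | None = None,
                    alpha: float = 0.05,
                    features: list[str] | None = None,
                    redundancy_threshold: float = 0.9,
                    apply_redundancy: bool = True) -> SelectionResult:
    """Discrete-state selection (M1): Kruskal-Wallis per state pair.

    Groups are per-subject segment means of the two states; a feature is
    preliminarily selected iff p < alpha in every pairwise comparison.
    """
    design = design or ComparisonDesign.discrete_default()
    if design.mode != "discrete":
        raise ValueError("discrete_select needs a discrete design")
    features = features or [c for c in registry.FEATURE_COLUMNS if c in fm.columns]
    sm = segment_means(fm, features)
    by_state = {st: g.groupby("subject")[features].mean()
                for st, g in sm.groupby("label")}
    decisions: dict[str, FeatureDecision] = {}
    for feat in features:
        d = FeatureDecision(feat)
        sig = True
        for a, b in design.pairs:
            ga = by_state[a][feat].dropna().to_numpy()
            gb = by_state[b][feat].dropna().to_numpy()
            key = f"{a} vs {b}"
            if ga.size < 2 or gb.size < 2 or (np.ptp(ga) == 0 and np.ptp(gb) == 0
                                              and ga[0] == gb[0]):
                p = 1.0
                d.tests[key] = "degenerate"
            else:
                p = float(stats.kruskal(ga, gb).pvalue)
                d.tests[key] = "kruskal_wallis"
            d.p_values[key] = p
            sig = sig and (p < alpha)
        d.significant = sig
        decisions[feat] = d
    result = SelectionResult("M1", alpha, decisions,
                             [f for f in features if decisions[f].significant])
    if apply_redundancy:
        redundancy_filter(result, fm, threshold=redundancy_threshold)
    return result


def redundancy_filter(result: SelectionResult, fm: pd.DataFrame,
                      threshold: float = 0.9) -> SelectionResult:
    """Greedy Pearson redundancy filter on the preliminary subset.

    Candidates are walked in canonical registry order; a feature is kept iff
    |r| with every already-kept feature is <= threshold on pooled
    window-level values.  A constant feature (correlation undefined) is
    kept and flagged.  Mutates and returns ``result``.
    """
    order = [f for f in registry.FEATURE_COLUMNS if f in result.decisions]
    candidates = [f for f in order if result.decisions[f].significant]
    kept: list[str] = []
    for feat in candidates:
        x = fm[feat].to_numpy(dtype=float)
        dec = result.decisions[feat]
        dec.discarded_redundant = False
        dec.partner = None
        dec.correlation = None
        if np.std(x) == 0:
            dec.constant = True
            kept.append(feat)
            continue
        redundant = False
        for other in kept:
            y = fm[other].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            mask = np.isfinite(x) & np.isfinite(y)
            r = float(np.corrcoef(x[mask], y[mask])[0, 1])
            if abs(r) > threshold:
                dec.discarded_redundant = True
                dec.partner = other
                dec.correlation = r
                redundant = True
                break
        if not redundant:
            kept.append(feat)
    result.final_subset = kept
    return result


def pca_reduce(fm: pd.DataFrame,
               group_dims: dict[str, int] | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-signal-group PCA (M2) on z-scored feature blocks.

    Returns the transformed matrix (metadata columns preserved, component
    columns named ``PC{i}_{SIG}``) and a report with loadings and
    explained-variance ratios per group.
    """
    group_dims = group_dims or {"ECG": 6, "BVP": 5, "GSR": 6}
    meta_cols = [c for c in ("subject", "segment", "label", "window") if c in fm.columns]
    out = fm[meta_cols].copy()
    report: dict[str, dict] = {}
    for sig, k in group_dims.items():
        cols = [c for c in registry.group_columns(sig) if c in fm.columns]
        if k > len(cols):
            raise ValueError(f"requested {k} components for {sig} but only "
                             f"{len(cols)} features")
        X = fm[cols].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd
        pca = PCA(n_components=k, svd_solver="full")
        Z = pca.fit_transform(Xz)
        for i in range(k):
            out[f"PC{i + 1}_{sig}"] = Z[:, i]
        report[sig] = {
            "columns": cols,
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
            "loadings": pca.components_.tolist(),
        }
    return out, report


# ---------------------------------------------------------------------------
# Published-annotation bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Significance/redundancy markers of a published selection table."""

    rows: pd.DataFrame   # columns: signal, feature, method, marker

    def __post_init__(self) -> None:
        required = {"signal", "feature", "method", "marker"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        bad = set(self.rows["marker"]) - set(MARKERS)
        if bad:
            raise ValueError(f"unknown markers: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, dtype=str).fillna("—")
        df["marker"] = df["marker"].str.strip().replace(
            {"*(-)": "*(—)", "-": "—", "*(--)": "*(—)"})
        return cls(df)

    @classmethod
    def bundled(cls) -> "AnnotationTable":
        """The marker table shipped with the package (transcribed printed table)."""
        with resources.as_file(resources.files("transfeat.data") / "table1.csv") as p:
            return cls.from_csv(p)


def selection_from_annotations(table: AnnotationTable, method: str) -> dict:
    """Selection bookkeeping for one method from its marker column.

    preliminary = rows marked "*" or "*(—)"; discarded = "*(—)";
    final = preliminary minus discarded, with per-signal final counts.
    """
    if method not in set(table.rows["method"]):
        raise ValueError(f"method {method!r} not present in annotation table")
    sub = table.rows[table.rows["method"] == method]
    prelim = sub[sub["marker"].isin(["*", "*(—)"])]
    discarded = sub[sub["marker"] == "*(—)"]
    final = prelim[prelim["marker"] == "*"]
    per_signal = final.groupby("signal")["feature"].count().to_dict()
    return {
        "method": method,
        "preliminary_count": int(len(prelim)),
        "discarded_count": int(len(discarded)),
        "final_count": int(len(final)),
        "per_signal_final": {s: int(per_signal.get(s, 0)) for s in registry.SIGNALS},
        "final_features": final["feature"].tolist(),
    }
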