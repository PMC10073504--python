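"""Per-window computation of the 39 physiological features.

ECG (15): MEANRR, SDNN, RMSSD, NN50, PNN50, HR, VLF/LF/HF band powers,
LF/HF ratio and multiscale sample entropy at scales 1-5 of the RR series.

BVP (12): pulse rate and the HRV analogues on the pulse-peak interval
series (SDNN, RMSSD, MEANRR, LF, HF), mean inter-onset width, mean
amplitude/width ratio (H_W), pulse-wave amplitude statistics
(MAXPA/STDPA/MEANPA) and the upper-envelope mean (HIGH).

GSR (12): tonic statistics (MEANT/STDT/AUCT), phasic statistics
(STDR/AUCR), response-event statistics (NUMP, MAXPA/MEANPA/STDPA,
MEANPR/STDPR) and total in-window spectral power (PSD).  Tonic and phasic
series are z-normalised per subject over the whole session before the
window statistics are taken (raw conductance mode is available), matching
the convention that conductance levels are only interpretable relative to
a subject's own baseline.

All standard deviations are sample standard deviations (n-1); NN50 counts
successive differences strictly greater than 50 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from . import registry
from .preprocess import (BeatAnnotations, EDAComponents, bandpass_filter,
                         decompose_eda, detect_pulses, detect_r_peaks,
                         make_windows, notch_filter, resample_gsr)
from .simulate import SubjectRecord

logger = logging.getLogger(__name__)

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def hrv_time(rr: np.ndarray) -> dict[str, float]:
    """Time-domain HRV statistics of the RR intervals inside one window."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        return {k: np.nan for k in ("MEANRR", "SDNN", "RMSSD", "NN50", "PNN50", "HR")}
    d = np.diff(rr)
    nn50 = int(np.sum(np.abs(d) > 0.050))
    return {
        "MEANRR": float(np.mean(rr)),
        "SDNN": float(np.std(rr, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "NN50": float(nn50),
        "PNN50": float(nn50 / (rr.size - 1)),
        "HR": float(60.0 / np.mean(rr)),
    }


def hrv_freq(rr: np.ndarray, resample_hz: float = 4.0,
             seg_len_s: float = 32.0) -> dict[str, float]:
    """Band powers of the interpolated, detrended tachogram (Welch).

    The RR series is placed at its cumulative beat times, cubic-interpolated
    onto a uniform grid, linearly detrended and analysed with a Hann-window
    Welch estimator (50% overlap).  Band powers integrate the PSD over
    VLF (<0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz).
    """
    rr = np.asarray(rr, dtype=float)
    out = {"VLF": np.nan, "LF": np.nan, "HF": np.nan, "LF_HF": np.nan}
    if rr.size < 4 or np.sum(rr) < 30.0:
        return out
    t = np.cumsum(rr)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if grid.size < 16:
        return out
    kind = "cubic" if rr.size >= 4 else "linear"
    tach = interpolate.interp1d(t, rr, kind=kind)(grid)
    tach = signal.detrend(tach, type="linear")
    nperseg = min(int(seg_len_s * resample_hz), len(tach))
    freqs, psd = signal.welch(tach, fs=resample_hz, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs > lo) & (freqs <= hi)
        return float(np.sum(psd[mask]) * df)

    out["VLF"] = band_power(*VLF_BAND)
    out["LF"] = band_power(*LF_BAND)
    out["HF"] = band_power(*HF_BAND)
    # HF below double-precision noise counts as zero power -> ratio undefined
    out["LF_HF"] = out["LF"] / out["HF"] if out["HF"] > 1e-20 else np.nan
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.2) -> float:
    """Sample entropy with Chebyshev distance, self-matches excluded.

    ``r`` defaults to ``r_factor`` times the sample standard deviation of
    ``x``.  Returns 0.0 for a constant series by convention and NaN
    (missing) when no template match extends to length m+1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return np.nan
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    if r is None:
        r = r_factor * sd
    # embeddings of length m and m+1 over the same n-m template starts
    nt = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # nt rows
    db = np.max(np.abs(emb_m[:, None, :] - emb_m[None, :, :]), axis=-1)
    da = np.max(np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]), axis=-1)
    iu = np.triu_indices(nt, k=1)
    b = int(np.sum(db[iu] <= r))
    iu1 = np.triu_indices(emb_m1.shape[0], k=1)
    a = int(np.sum(da[iu1] <= r))
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def multiscale_entropy(x: np.ndarray, scales: range = range(1, 6),
                       m: int = 2, r_factor: float = 0.2) -> dict[str, float]:
    """Sample entropy of non-overlapping block means at each scale.

    The tolerance r is fixed from the scale-1 series so entropy changes
    across scales reflect structure, not shrinking variance.
    """
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    r = 0.2 * sd if sd > 0 else None
    for tau in scales:
        nb = x.size // tau
        if nb < m + 2:
            out[f"MSE{tau}"] = np.nan
            continue
        coarse = x[: nb * tau].reshape(nb, tau).mean(axis=1)
        if sd == 0:
            out[f"MSE{tau}"] = 0.0
        else:
            out[f"MSE{tau}"] = sample_entropy(coarse, m=m, r=r, r_factor=r_factor)
    return out


def ecg_features(rr: np.ndarray) -> dict[str, float]:
    """All 15 ECG features for the RR intervals of one window."""
    out = hrv_time(rr)
    out.update(hrv_freq(rr))
    out.update(multiscale_entropy(rr))
    return {f"{k}_ECG": v for k, v in out.items()}


def bvp_features(beats: BeatAnnotations, window: tuple[float, float]) -> dict[str, float]:
    """All 12 BVP features from the pulse annotations inside one window."""
    lo, hi = window
    names = ["PR", "SDNN", "RMSSD", "MEANRR", "LF", "HF", "WIDTH", "H_W",
             "MAXPA", "STDPA", "MEANPA", "HIGH"]
    out = {n: np.nan for n in names}
    pt = beats.peak_times_s if beats.peak_times_s is not None else beats.event_times_s
    in_win = (pt >= lo) & (pt < hi)
    idx = np.flatnonzero(in_win)
    if idx.size >= 3:
        intervals = np.diff(pt[idx])
        t = hrv_time(intervals)
        out["PR"] = t["HR"]
        out["SDNN"] = t["SDNN"]
        out["RMSSD"] = t["RMSSD"]
        out["MEANRR"] = t["MEANRR"]
        f = hrv_freq(intervals)
        out["LF"], out["HF"] = f["LF"], f["HF"]
        if beats.amplitudes is not None:
            amps = beats.amplitudes[idx]
            out["MAXPA"] = float(np.max(amps))
            out["MEANPA"] = float(np.mean(amps))
            out["STDPA"] = float(np.std(amps, ddof=1)) if amps.size > 1 else 0.0
        if beats.peak_values is not None:
            out["HIGH"] = float(np.mean(beats.peak_values[idx]))
        if beats.onset_times_s is not None and beats.widths_s is not None:
            # per-pulse widths pair pulse i with the onset-to-onset gap after it
            widx = idx[idx < len(beats.widths_s)]
            if widx.size:
                widths = beats.widths_s[widx]
                out["WIDTH"] = float(np.mean(widths))
                if beats.amplitudes is not None:
                    ratio = beats.amplitudes[widx] / widths
                    out["H_W"] = float(np.mean(ratio))
    return {f"{k}_BVP": v for k, v in out.items()}


def gsr_features(eda: EDAComponents, window: tuple[float, float],
                 raw: np.ndarray | None = None,
                 norm_stats: dict[str, tuple[float, float]] | None = None,
                 t0_s: float = 0.0) -> dict[str, float]:
    """All 12 GSR features for one window.

    ``norm_stats`` holds per-subject (mean, sd) for the tonic and phasic
    series; when given, window statistics of those series are computed on
    z-normalised values.  Event amplitudes and rise times stay in raw units.
    ``raw`` is the 4-Hz conductance signal used for the PSD feature
    (defaults to tonic + phasic).
    """
    lo, hi = window
    rate = eda.rate_hz
    i0 = int(round((lo - t0_s) * rate))
    i1 = int(round((hi - t0_s) * rate))
    tonic = eda.tonic[i0:i1]
    phasic = eda.phasic[i0:i1]
    if raw is None:
        raw_win = tonic + phasic
    else:
        raw_win = raw[i0:i1]
    names = ["MEANT", "STDT", "AUCT", "STDR", "AUCR", "NUMP", "MAXPA",
             "MEANPA", "STDPA", "MEANPR", "STDPR", "PSD"]
    out = {n: np.nan for n in names}
    if tonic.size < 2:
        return {f"{k}_GSR": v for k, v in out.items()}
    if norm_stats:
        mt, st = norm_stats["tonic"]
        mp, sp = norm_stats["phasic"]
        tonic = (tonic - mt) / st if st > 0 else tonic - mt
        phasic = (phasic - mp) / sp if sp > 0 else phasic - mp
    dx = 1.0 / rate
    out["MEANT"] = float(np.mean(tonic))
    out["STDT"] = float(np.std(tonic, ddof=1))
    out["AUCT"] = float(np.trapezoid(tonic, dx=dx))
    out["STDR"] = float(np.std(phasic, ddof=1))
    out["AUCR"] = float(np.trapezoid(phasic, dx=dx))
    ev = [e for e in eda.scr_events if lo <= e[0] < hi]
    out["NUMP"] = float(len(ev))
    if ev:
        amps = np.array([e[2] for e in ev])
        rises = np.array([e[3] for e in ev])
        out["MAXPA"] = float(np.max(amps))
        out["MEANPA"] = float(np.mean(amps))
        out["STDPA"] = float(np.std(amps, ddof=1)) if amps.size > 1 else 0.0
        out["MEANPR"] = float(np.mean(rises))
        out["STDPR"] = float(np.std(rises, ddof=1)) if rises.size > 1 else 0.0
    else:
        out["MAXPA"] = out["MEANPA"] = out["STDPA"] = 0.0
        out["MEANPR"] = out["STDPR"] = 0.0
    freqs, psd = signal.periodogram(raw_win, fs=rate, detrend="constant")
    out["PSD"] = float(np.sum(psd) * (freqs[1] - freqs[0]))
    return {f"{k}_GSR": v for k, v in out.items()}


# ---------------------------------------------------------------------------
# Cohort-level extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """Knobs of the extraction pipeline."""

    window_len_s: float = 60.0
    step_s: float = 1.0
    filter_ecg: bool = True
    filter_bvp: bool = True
    notch_hz: float | None = 50.0
    gsr_rate_hz: float = 4.0
    normalize_gsr: bool = True
    include_labels: tuple[str, ...] | None = None   # None = all segments
    max_missing_frac: float = 0.20
    eda_kwargs: dict = field(default_factory=dict)


def extract_subject_features(subject: SubjectRecord,
                             config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Run preprocessing + all 39 features for every window of one subject."""
    cfg = config or ExtractionConfig()
    ecg = subject.recordings["ecg"]
    bvp = subject.recordings["bvp"]
    gsr = subject.recordings["gsr"]

    if cfg.filter_ecg:
        ecg = bandpass_filter(ecg)
        if cfg.notch_hz:
            ecg = notch_filter(ecg, cfg.notch_hz)
    if cfg.filter_bvp:
        bvp = bandpass_filter(bvp)
        if cfg.notch_hz:
            bvp = notch_filter(bvp, cfg.notch_hz)

    r = detect_r_peaks(ecg)
    beat_times = r.event_times_s
    pulses = detect_pulses(bvp)

    gsr4 = resample_gsr(gsr, cfg.gsr_rate_hz) if gsr.rate_hz != cfg.gsr_rate_hz else gsr
    eda = decompose_eda(gsr4, **cfg.eda_kwargs)
    norm_stats = None
    if cfg.normalize_gsr:
        norm_stats = {
            "tonic": (float(np.mean(eda.tonic)), float(np.std(eda.tonic, ddof=1))),
            "phasic": (float(np.mean(eda.phasic)), float(np.std(eda.phasic, ddof=1))),
        }

    rows = []
    for seg_idx, (label, start, end) in enumerate(subject.timeline.segments):
        if cfg.include_labels is not None and label not in cfg.include_labels:
            continue
        grid = make_windows((start, end), cfg.window_len_s, cfg.step_s)
        for w_idx, (lo, hi) in enumerate(grid.windows):
            # RR intervals whose terminating beat lies in the window
            i0, i1 = np.searchsorted(beat_times, [lo, hi])
            i0 = max(i0, 1)
            rr = np.diff(beat_times[i0 - 1:i1])
            row = {"subject": subject.subject_id, "segment": seg_idx,
                   "label": label, "window": w_idx}
            row.update(ecg_features(rr))
            row.update(bvp_features(pulses, (lo, hi)))
            row.update(gsr_features(eda, (lo, hi), raw=gsr4.samples,
                                    norm_stats=norm_stats, t0_s=gsr4.t0_s))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[["subject", "segment", "label", "window"] + list(registry.FEATURE_COLUMNS)]


def extract_feature_matrix(subjects: list[SubjectRecord],
                           config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature matrix over a whole cohort with median imputation.

    Missing window values are imputed by the per-(subject, segment) median
    of the feature; the imputation count is logged.  A feature column with
    more than ``max_missing_frac`` missing values fails hard.
    """
    cfg = config or ExtractionConfig()
    fm = pd.concat([extract_subject_features(s, cfg) for s in subjects],
                   ignore_index=True)
    feat_cols = list(registry.FEATURE_COLUMNS)
    missing = fm[feat_cols].isna()
    frac = missing.mean()
    bad = frac[frac > cfg.max_missing_frac]
    if not bad.empty:
        raise ValueError(
            "feature columns exceed the missing-value budget "
            f"({cfg.max_missing_frac:.0%}): " +
            ", ".join(f"{c}={v:.1%}" for c, v in bad.items()))
    n_missing = int(missing.to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing feature values by per-subject-segment median",
                    n_missing)
        med = fm.groupby(["subject", "segment"])[feat_cols].transform("median")
        fm[feat_cols] = fm[feat_cols].fillna(med)
        # residual NaN (whole segment missing) -> per-subject median
        if fm[feat_cols].isna().any().any():
            med2 = fm.groupby("subject")[feat_cols].transform("median")
            fm[feat_cols] = fm[feat_cols].fillna(med2)
    return fm
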