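"""PSM filtration and evaluation: FIC cutoff, target-decoy FDR, ROC sweeps,
automated confidence classification, and cross-dataset loss rates.

Target-decoy FDR is implemented in its plain "manually calculated" form,
FDR(s) = #decoys >= s / #targets >= s without pseudocount, because that is
the quantity whose instability on small datasets motivates the FIC
criterion: with only dozens of target PSMs a single well-scoring decoy
forces the 1% threshold above genuine identifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ISOTOPE_SPACING, ChimaError
from .search import PSM, DEFAULT_FRAGMENT_TOL_PPM
from .spectra import Spectrum

__all__ = [
    "FdrResult",
    "RocCurve",
    "CrossRefResult",
    "filter_fic",
    "target_decoy_fdr",
    "roc_compare",
    "classify_confidence",
    "cross_reference",
]


@dataclass
class FdrResult:
    level: float
    threshold: Optional[float]  # smallest score passing the level; None if none
    achieved_fdr: Optional[float]
    target_scores: np.ndarray
    decoy_scores: np.ndarray
    qvalues_targets: np.ndarray  # aligned with target_scores order
    no_decoys: bool = False

    def accepts(self, score: float) -> bool:
        return self.threshold is not None and score >= self.threshold


def filter_fic(psms: Sequence[PSM], cutoff: float = 0.5) -> list[PSM]:
    """Keep PSMs with FIC >= cutoff (inclusive boundary), order-stable."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"FIC cutoff must be in [0, 1], got {cutoff}")
    return [p for p in psms if p.fic >= cutoff]


def _fdr_at(scores_t: np.ndarray, scores_d: np.ndarray, s: float) -> float:
    n_t = int((scores_t >= s).sum())
    n_d = int((scores_d >= s).sum())
    if n_d == 0:
        return 0.0
    if n_t == 0:
        return np.inf
    return n_d / n_t


def target_decoy_fdr(
    psms: Optional[Sequence[PSM]] = None,
    *,
    target_scores: Optional[Sequence[float]] = None,
    decoy_scores: Optional[Sequence[float]] = None,
    level: float = 0.01,
) -> FdrResult:
    """Threshold and q-values from the decoy/target score ratio.

    The q-value of score s is the minimum FDR over all thresholds t <= s
    (every threshold that still admits the PSM); the reported threshold is
    the smallest distinct score whose q-value meets the level. With no
    decoy hits present the result is flagged and the threshold undefined.
    """
    if psms is not None:
        target_scores = [p.rank_score for p in psms if not p.is_decoy]
        decoy_scores = [p.rank_score for p in psms if p.is_decoy]
    t = np.asarray(list(target_scores), dtype=float)
    d = np.asarray(list(decoy_scores), dtype=float)
    if len(d) == 0:
        return FdrResult(
            level=level,
            threshold=None,
            achieved_fdr=None,
            target_scores=t,
            decoy_scores=d,
            qvalues_targets=np.zeros(len(t)),
            no_decoys=True,
        )
    distinct = np.unique(np.concatenate([t, d]))  # ascending
    fdr_at = {s: _fdr_at(t, d, s) for s in distinct}
    # q(s) = min FDR over thresholds <= s: running minimum from the bottom up.
    qvals = {}
    running = np.inf
    for s in distinct:
        running = min(running, fdr_at[s])
        qvals[s] = running
    threshold = None
    for s in distinct:  # ascending => first hit is the smallest score
        if qvals[s] <= level:
            threshold = float(s)
            break
    achieved = fdr_at[threshold] if threshold is not None else None
    q_targets = np.array([qvals[s] for s in t]) if len(t) else np.zeros(0)
    return FdrResult(
        level=level,
        threshold=threshold,
        achieved_fdr=achieved,
        target_scores=t,
        decoy_scores=d,
        qvalues_targets=q_targets,
    )


@dataclass
class RocCurve:
    strategy: str  # "fdr-sweep" | "fic-sweep"
    points: list  # (cutoff, fpr, tpr), strict to loose

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["cutoff", "fpr", "tpr"]).assign(
            strategy=self.strategy
        )


def _rates(accepted: np.ndarray, truth: np.ndarray) -> tuple:
    n_true = int(truth.sum())
    n_false = int((~truth).sum())
    tpr = float((accepted & truth).sum() / n_true) if n_true else np.nan
    fpr = float((accepted & ~truth).sum() / n_false) if n_false else 0.0
    return fpr, tpr


def roc_compare(
    psms: Sequence[PSM],
    truth_labels: Mapping[tuple, bool],
    fdr_grid: Optional[Sequence[float]] = None,
    fic_grid: Optional[Sequence[float]] = None,
) -> tuple:
    """ROC curves for FDR-level and FIC-cutoff sweeps, strict to loose.

    ``truth_labels`` maps (scan_id, form key) -> bool over the labeled
    (target) PSMs; decoy PSMs contribute only to FDR thresholding. Both
    curves get explicit accept-nothing (0,0) and accept-everything (1,1)
    endpoints so they are comparable step functions.
    """
    labeled = [p for p in psms if (p.scan_id, p.form.key()) in truth_labels]
    if not labeled:
        raise ChimaError("no labeled PSMs to build ROC curves from")
    truth = np.array([truth_labels[(p.scan_id, p.form.key())] for p in labeled])
    if not truth.any():
        warnings.warn("no true positives among labeled PSMs; TPR undefined")
    if fdr_grid is None:
        fdr_grid = np.arange(0.01, 1.0001, 0.01)  # 1% .. 100%
    if fic_grid is None:
        fic_grid = np.arange(1.0, -0.0001, -0.01)  # 100% .. 0%

    fdr_points = [(0.0, 0.0, 0.0)]
    for level in fdr_grid:
        res = target_decoy_fdr(psms, level=float(level))
        accepted = np.array(
            [res.threshold is not None and p.rank_score >= res.threshold for p in labeled]
        )
        fpr, tpr = _rates(accepted, truth)
        fdr_points.append((float(level), fpr, tpr))
    fdr_points.append((1.0, 1.0, 1.0))

    fic_points = [(1.0 + 1e-9, 0.0, 0.0)]
    for cutoff in fic_grid:
        accepted = np.array([p.fic >= cutoff for p in labeled])
        fpr, tpr = _rates(accepted, truth)
        fic_points.append((float(cutoff), fpr, tpr))
    fic_points.append((0.0, 1.0, 1.0))

    def monotone(points):
        out = []
        best_fpr = best_tpr = 0.0
        for cutoff, fpr, tpr in points:
            best_fpr = max(best_fpr, fpr)
            best_tpr = max(best_tpr, tpr if not np.isnan(tpr) else 0.0)
            out.append((cutoff, best_fpr, best_tpr))
        return out

    return (
        RocCurve("fdr-sweep", monotone(fdr_points)),
        RocCurve("fic-sweep", monotone(fic_points)),
    )


def _isotope_companions(
    spectrum: Spectrum,
    matched_peaks: Mapping[int, int],  # peak index -> fragment charge
    frag_tol_ppm: float,
) -> dict:
    """peak index -> companion peak index at +ISOTOPE_SPACING/z, if present."""
    mz = spectrum.mz
    out = {}
    for j, z in matched_peaks.items():
        target = mz[j] + ISOTOPE_SPACING / z
        tol = target * frag_tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        if hi > lo:
            cand = range(lo, hi)
            out[j] = int(min(cand, key=lambda k: abs(mz[k] - target)))
    return out


def classify_confidence(
    psm: PSM,
    spectrum: Spectrum,
    *,
    noise_rel_intensity: float = 0.05,
    isotope_fraction: float = 0.5,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> str:
    """Automated spectrum-quality triage: ``"high"`` or ``"moderate"``.

    High confidence requires all three checks to pass:

    (i)   no unexplained peak above the precursor m/z with relative
          intensity over ``noise_rel_intensity`` of the base peak;
    (ii)  at least ``isotope_fraction`` of the top-10 matched peaks carry a
          +1 isotope companion at +1.00335/z within the fragment tolerance;
    (iii) no unexplained loud peak beyond the largest matched fragment m/z.

    Isotope companions of matched peaks count as explained for (i)/(iii).
    These are triage flags approximating manual spectrum scrutiny, not
    verdicts.
    """
    if not psm.assignments:
        return "moderate"
    mz = spectrum.mz
    inten = spectrum.intensity
    base = spectrum.base_peak_intensity
    loud = inten > noise_rel_intensity * base

    matched_peaks: dict = {}
    for a in psm.assignments.values():
        prev = matched_peaks.get(a.peak_index)
        if prev is None or a.charge < prev:
            matched_peaks[a.peak_index] = a.charge
    companions = _isotope_companions(spectrum, matched_peaks, frag_tol_ppm)
    explained = set(matched_peaks) | set(companions.values())

    # (i) loud unexplained peaks above the precursor
    for j in range(len(mz)):
        if j not in explained and loud[j] and mz[j] > psm.precursor_mz:
            return "moderate"
    # (ii) isotope evidence on the strongest matched peaks
    top = sorted(matched_peaks, key=lambda j: -inten[j])[:10]
    with_iso = sum(1 for j in top if j in companions)
    if top and with_iso / len(top) < isotope_fraction:
        return "moderate"
    # (iii) loud unexplained peaks beyond the largest matched fragment
    max_frag_mz = max(mz[j] for j in matched_peaks)
    for j in range(len(mz)):
        if j not in explained and loud[j] and mz[j] > max_frag_mz:
            return "moderate"
    return "high"


@dataclass
class CrossRefResult:
    keys: list  # (sequence, ((index, mod name), ...))
    detected: pd.DataFrame  # bool, index=keys, columns=datasets
    missed: pd.DataFrame  # bool, same shape
    loss_rate: dict  # dataset -> float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ds in self.detected.columns:
            total = int(self.detected[ds].sum() + self.missed[ds].sum())
            rows.append(
                {
                    "dataset": ds,
                    "detected": int(self.detected[ds].sum()),
                    "missed": int(self.missed[ds].sum()),
                    "verified_total": total,
                    "loss_rate": self.loss_rate[ds],
                }
            )
        return pd.DataFrame(rows)


def cross_reference(
    run_results: Mapping[str, Sequence[PSM]],
    spectra: Mapping[str, Sequence[Spectrum]],
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 2.0,
) -> CrossRefResult:
    """Loss rates by cross-referencing accepted peptide forms across datasets.

    The union of accepted (sequence, mod-site) keys defines the verified
    forms. A dataset "misses" a key it did not accept only when its own
    raw spectra contain a precursor within ``mz_tol_ppm`` and
    ``rt_tol_min`` of another dataset's accepted PSM for that key — i.e.
    evidence the peptide was there to be found. loss_rate = missed /
    (detected + missed).
    """
    if len(run_results) < 2:
        raise ValueError("cross-referencing needs at least two datasets")
    evidence: dict = {}
    detected: dict = {}
    for ds, psms in run_results.items():
        for p in psms:
            key = p.form.key()
            detected.setdefault(key, set()).add(ds)
            evidence.setdefault(key, []).append(
                (p.precursor_mz, p.retention_time)
            )
    keys = sorted(detected)
    datasets = list(run_results)
    det = pd.DataFrame(False, index=pd.Index(range(len(keys))), columns=datasets)
    mis = pd.DataFrame(False, index=pd.Index(range(len(keys))), columns=datasets)

    def spectrum_supports(ds: str, key) -> bool:
        refs = evidence[key]
        for sp in spectra.get(ds, []):
            for ref_mz, ref_rt in refs:
                if abs(sp.precursor_mz - ref_mz) / ref_mz * 1e6 > mz_tol_ppm:
                    continue
                if ref_rt is None or sp.retention_time is None:
                    warnings.warn(
                        f"dataset {ds}: retention time missing, RT criterion skipped"
                    )
                    return True
                if abs(sp.retention_time - ref_rt) <= rt_tol_min:
                    return True
        return False

    for i, key in enumerate(keys):
        for ds in datasets:
            if ds in detected[key]:
                det.loc[i, ds] = True
            elif spectrum_supports(ds, key):
                mis.loc[i, ds] = True
    loss = {}
    for ds in datasets:
        total = int(det[ds].sum() + mis[ds].sum())
        loss[ds] = float(mis[ds].sum() / total) if total else 0.0
    return CrossRefResult(keys=keys, detected=det, missed=mis, loss_rate=loss)
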