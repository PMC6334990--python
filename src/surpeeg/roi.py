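"""ROI extraction and step-wise hierarchical model comparison.

Regions of interest are defined from the whole-head cluster results: each
significant effect contributes the time span of its cluster and the (at
most) five electrodes with the largest summed |t| over that span; effects
whose chosen electrodes straddle the montage midline (x = 0) are split into
a left and a right ROI.  Per-trial amplitudes averaged over an ROI are then
modeled hierarchically, and four step-wise questions are asked of every ROI:

1. does CFG surprisal improve fit beyond Ngram and SRN?
2. does Ngram improve fit beyond CFG?
3. does SRN improve fit beyond CFG?
4. does SRN improve fit beyond Ngram?

Each question compares a baseline (controls + word class + the competing
surprisal terms and their word-class interactions) against that baseline
plus the tested term alone, and plus the tested term and its word-class
interaction.  Differences in WAIC larger than twice their standard error are
flagged, with positive differences favoring the larger model.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import PermutationResult, TMap
from .hierbayes import (
    ConvergenceError,
    GibbsConfig,
    HierFit,
    WAICResult,
    compare_waic,
    fit_hier_arrays,
    waic,
)
from .montage import Montage
from .simulate import EpochSet

__all__ = [
    "ROIDefinition",
    "ComparisonLedger",
    "CONTROL_PREDICTORS",
    "HYPOTHESES",
    "define_rois",
    "extract_roi",
    "fit_hier",
    "stepwise_compare",
]

CONTROL_PREDICTORS = (
    "sentence_order",
    "word_order",
    "frq",
    "frq_prev",
    "frq_next",
    "sound_power",
)

#: hypothesis id -> (tested surprisal term, competing surprisal terms)
HYPOTHESES: dict[int, tuple[str, tuple[str, ...]]] = {
    1: ("surprisal_CFG", ("surprisal_Ngram", "surprisal_SRN")),
    2: ("surprisal_Ngram", ("surprisal_CFG",)),
    3: ("surprisal_SRN", ("surprisal_CFG",)),
    4: ("surprisal_SRN", ("surprisal_Ngram",)),
}

#: by-subject random-effect terms (intercept plus these slopes)
RANDOM_SLOPES = ("sentence_order", "word_class")

MAX_ROI_ELECTRODES = 5


@dataclass(frozen=True)
class ROIDefinition:
    """Electrode subset and time window distilled from one significant effect."""

    id: str
    electrodes: tuple[int, ...]
    window: tuple[float, float]  # seconds
    source_effect: str
    sign: int

    def __post_init__(self) -> None:
        if len(self.electrodes) > MAX_ROI_ELECTRODES:
            raise ValueError(f"ROI limited to {MAX_ROI_ELECTRODES} electrodes")


def define_rois(
    results: dict[str, tuple[PermutationResult, TMap]],
    montage: Montage,
    times: np.ndarray,
) -> list[ROIDefinition]:
    """One or two ROIs per significant cluster of each whole-head effect.

    Electrodes are ranked by summed |t| over the cluster's time span; the top
    five are kept.  If the kept electrodes lie on both sides of the midline
    the ROI is split in two (suffix ``-L`` / ``-R``).  Returns an empty list
    (with a warning) when nothing is significant.
    """
    rois: list[ROIDefinition] = []
    for effect, (perm_result, tmap) in results.items():
        for ci, cl in enumerate(perm_result.significant()):
            t0, t1 = cl.sample_range
            window = (float(times[t0]), float(times[t1]))
            electrodes = sorted(cl.electrodes)
            span_abs_t = np.abs(tmap.t[:, t0 : t1 + 1]).sum(axis=1)
            ranked = sorted(electrodes, key=lambda e: (-span_abs_t[e], e))
            chosen = ranked[:MAX_ROI_ELECTRODES]
            xs = montage.positions[np.array(chosen), 0]
            base_id = f"{effect}-c{ci + 1}"
            if (xs < 0).any() and (xs >= 0).any():
                left = tuple(sorted(e for e in chosen if montage.positions[e, 0] < 0))
                right = tuple(sorted(e for e in chosen if montage.positions[e, 0] >= 0))
                rois.append(
                    ROIDefinition(f"{base_id}-L", left, window, effect, cl.sign)
                )
                rois.append(
                    ROIDefinition(f"{base_id}-R", right, window, effect, cl.sign)
                )
            else:
                rois.append(
                    ROIDefinition(base_id, tuple(sorted(chosen)), window, effect, cl.sign)
                )
    if not rois:
        import warnings

        warnings.warn("no significant clusters; ROI list is empty", stacklevel=2)
    return rois


def _scale_pm10(x: np.ndarray) -> np.ndarray:
    """Center and scale so values fall in [-10, 10]."""
    c = x - x.mean()
    m = np.abs(c).max()
    return c if m == 0 else 10.0 * c / m


def extract_roi(
    epochs: EpochSet, roi: ROIDefinition, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-(subject, retained trial) mean ROI amplitude with joined predictors.

    All predictors are centered and scaled into +-10; word class is sum-coded
    (content +1, function -1) and then centered like the rest.
    """
    i0 = epochs.time_index(roi.window[0])
    i1 = epochs.time_index(roi.window[1])
    if i1 < i0:
        raise ValueError("empty ROI time window")
    elec = np.array(roi.electrodes)
    roi_amp = epochs.data[:, :, elec, i0 : i1 + 1].mean(axis=(2, 3))  # (S, W)

    frames = []
    for s in range(epochs.n_subjects):
        keep = np.flatnonzero(epochs.mask[s])
        sub = table.iloc[keep].copy()
        sub.insert(0, "subject", s)
        sub["amplitude"] = roi_amp[s, keep]
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)

    out = df[["subject", "amplitude"]].copy()
    out["word_class"] = _scale_pm10(
        np.where(df["word_class"] == "content", 1.0, -1.0)
    )
    for col in df.columns:
        if col in ("subject", "amplitude", "word_class", "tag"):
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            out[col] = _scale_pm10(df[col].to_numpy(float))
    return out


def _design_for_terms(
    data: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[term].to_numpy(float))
        names.append(term)
    return np.column_stack(cols), tuple(names)


def fit_hier(
    data: pd.DataFrame,
    terms: tuple[str, ...],
    config: GibbsConfig | None = None,
    check: bool = True,
) -> HierFit:
    """Hierarchical fit of ROI amplitudes on the given population terms.

    Interactions are written ``"a:b"`` and multiply the already-scaled
    columns.  Random effects are a by-subject intercept plus by-subject
    slopes for sentence order and word class.
    """
    X, names = _design_for_terms(data, tuple(terms))
    W_cols = [np.ones(len(data))] + [
        data[c].to_numpy(float) for c in RANDOM_SLOPES
    ]
    W = np.column_stack(W_cols)
    return fit_hier_arrays(
        y=data["amplitude"].to_numpy(float),
        X=X,
        W=W,
        subject=data["subject"].to_numpy(),
        columns=names,
        re_columns=("intercept",) + RANDOM_SLOPES,
        config=config,
        check=check,
    )


@dataclass
class ComparisonLedger:
    """Rows of (roi, hypothesis, candidate, delta_waic, se, significant)."""

    rows: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.rows.to_dict(orient="records"), indent=1),
            encoding="utf-8",
        )

    def significant(self) -> pd.DataFrame:
        return self.rows[self.rows["significant"] == True]  # noqa: E712


def _term_seed(master_seed: int, roi_id: str, terms: tuple[str, ...]) -> int:
    key = f"{master_seed}|{roi_id}|{'+'.join(sorted(terms))}"
    return zlib.crc32(key.encode()) % (2**31 - 1)


def stepwise_compare(
    roi_data: dict[str, pd.DataFrame],
    seed: int = 0,
    config: GibbsConfig | None = None,
    hypotheses: dict[int, tuple[str, tuple[str, ...]]] | None = None,
) -> ComparisonLedger:
    """Run the four step-wise WAIC comparisons in every ROI.

    Produces n_rois x n_hypotheses x 2 rows (candidate adds the tested main
    effect, or the main effect plus its word-class interaction).  A fit that
    fails to converge marks its rows ``failed`` and the schedule continues.
    Fits are cached per (ROI, term set); each fit's sampler seed derives
    deterministically from the master seed, the ROI id and the term set.
    """
    config = config or GibbsConfig()
    hypotheses = hypotheses or HYPOTHESES
    records = []
    for roi_id, data in roi_data.items():
        cache: dict[tuple[str, ...], WAICResult | None] = {}

        def fit_waic(terms: tuple[str, ...]) -> WAICResult | None:
            key = tuple(sorted(terms))
            if key not in cache:
                cfg = GibbsConfig(
                    chains=config.chains,
                    warmup=config.warmup,
                    draws=config.draws,
                    beta_sd=config.beta_sd,
                    scale_prior=config.scale_prior,
                    rhat_limit=config.rhat_limit,
                    seed=_term_seed(seed, roi_id, key),
                )
                try:
                    fit = fit_hier(data, terms, config=cfg)
                    cache[key] = waic(fit.loglik)
                except (ConvergenceError, np.linalg.LinAlgError):
                    cache[key] = None
            return cache[key]

        for hyp_id, (tested, competing) in hypotheses.items():
            base_terms = (
                CONTROL_PREDICTORS
                + ("word_class",)
                + competing
                + tuple(f"{c}:word_class" for c in competing)
            )
            base = fit_waic(base_terms)
            for candidate, extra in (
                ("main", (tested,)),
                ("main+interaction", (tested, f"{tested}:word_class")),
            ):
                cand = fit_waic(base_terms + extra)
                rec = {
                    "roi": roi_id,
                    "hypothesis": hyp_id,
                    "candidate": candidate,
                    "tested": tested,
                }
                if base is None or cand is None:
                    rec.update(
                        delta_waic=np.nan, se=np.nan, significant=False, failed=True
                    )
                else:
                    delta, se = compare_waic(base, cand)
                    rec.update(
                        delta_waic=delta,
                        se=se,
                        significant=bool(delta > 2.0 * se),
                        failed=False,
                    )
                records.append(rec)
    return ComparisonLedger(rows=pd.DataFrame(records))
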