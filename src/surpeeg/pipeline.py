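"""End-to-end synthetic experiment: corpus -> surprisal -> EEG -> inference.

One config drives every stage: sample a POS corpus from a grammar, train the
three context models and score per-word surprisal, simulate multi-subject
epochs with configurable injected effects, run the per-subject single-trial
regressions and the group cluster permutation test for each surprisal model
and word class, distill ROIs from the significant effects, and run the
step-wise WAIC comparisons.  A master seed expands deterministically into
per-stage seeds, so identical configs produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import fixtures
from .behavioral import behavioral_threshold
from .cluster import paired_t_map, permutation_test
from .grammar import load_grammar, sample_corpus
from .hierbayes import GibbsConfig
from .montage import Montage, make_montage
from .ngram import train_ngram
from .rerp import build_design, fit_null, fit_single_trial
from .roi import CONTROL_PREDICTORS as CONTROLS
from .roi import define_rois, extract_roi, stepwise_compare
from .simulate import (
    Effect,
    EpochSet,
    build_predictor_table,
    effect_amplitude_for_snr,
    lowpass_epochs,
    reject_trials,
    simulate_epochs,
)
from .srn import SRNConfig, train_srn
from .surprisal import (
    accuracy_report,
    cfg_surprisal,
    compare_mean_surprisal,
    ngram_surprisal,
    null_surprisal,
    srn_surprisal,
    surprisal_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "spatial_pattern", "DEMO_CONFIG"]

log = logging.getLogger("surpeeg.pipeline")

#: named spatial-pattern centers on the unit disk (anterior = +y)
_PATTERN_CENTERS = {
    "anterior": (0.0, 0.6),
    "posterior": (0.0, -0.6),
    "central": (0.0, 0.0),
    "left-anterior": (-0.45, 0.5),
    "right-anterior": (0.45, 0.5),
}


def spatial_pattern(montage: Montage, kind: str, width: float = 0.35) -> np.ndarray:
    """Gaussian spatial weights (max 1) centered on a named scalp region."""
    if kind not in _PATTERN_CENTERS:
        raise ValueError(f"unknown spatial pattern {kind!r}")
    center = np.array(_PATTERN_CENTERS[kind])
    d2 = ((montage.positions - center) ** 2).sum(axis=1)
    w = np.exp(-0.5 * d2 / width**2)
    return w / w.max()


@dataclass(frozen=True)
class EffectConfig:
    predictor: str
    pattern: str = "anterior"
    center: float = 0.35  # s
    width: float = 0.06  # s
    snr: float = 1.0
    word_class: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Full experiment configuration; the master seed determines all stages."""

    seed: int = 0
    grammar_path: str | None = None  # None -> bundled story grammar
    n_sentences: int = 84
    max_len: int = 60
    n_electrodes: int = 16
    montage_k: int = 4
    fs: float = 100.0
    n_subjects: int = 8
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    subject_gain_sd: float = 0.2
    rejection_fraction: float = 0.135
    lowpass_hz: float = 40.0
    effects: tuple[EffectConfig, ...] = ()
    srn_hidden: int = 32
    srn_epochs: int = 30
    srn_learning_rate: float = 0.3
    n_perm: int = 500
    cluster_alpha: float = 0.05
    cluster_threshold: float = 0.05
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    behavioral_questions: int = 8
    behavioral_choices: int = 4
    behavioral_alpha: float = 0.05
    behavioral_accuracy: float = 0.75  # simulated per-question accuracy
    include_flagged_subjects: bool = False
    run_comparison: bool = True

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        effects = tuple(EffectConfig(**e) for e in d.pop("effects", []))
        return cls(effects=effects, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["effects"] = [dataclasses.asdict(e) for e in self.effects]
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        names = (
            "corpus",
            "srn",
            "table",
            "epochs",
            "reject",
            "null",
            "cluster",
            "sampler",
            "behavioral",
        )
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


#: the demo configuration: small montage and subject count, injected
#: content-word CFG-surprisal effect over anterior electrodes at 200-500 ms
DEMO_CONFIG = PipelineConfig(
    seed=1,
    n_sentences=84,
    n_subjects=8,
    n_electrodes=16,
    fs=100.0,
    n_perm=500,
    warmup=300,
    draws=300,
    srn_epochs=20,
    effects=(
        EffectConfig(
            predictor="surprisal_CFG",
            pattern="anterior",
            center=0.35,
            width=0.06,
            snr=1.0,
            word_class="content",
        ),
    ),
)

SURPRISAL_MODELS = ("Ngram", "SRN", "CFG")
WORD_CLASSES = ("content", "function")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage, write per-stage artifacts, return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = config.stage_seeds()
    chash = config.config_hash()
    summary: dict[str, Any] = {"config_hash": chash, "seed": config.seed}

    def stage(name):
        log.info("stage %s start (seed %s)", name, seeds.get(name, "-"))
        return time.time()

    def done(name, t0):
        log.info("stage %s done in %.1f s", name, time.time() - t0)

    try:
        # -- corpus --------------------------------------------------------
        t0 = stage("corpus")
        if config.grammar_path:
            grammar = load_grammar(config.grammar_path)
            word_classes = fixtures.story_word_classes()
        else:
            grammar = fixtures.story_grammar()
            word_classes = fixtures.story_word_classes()
        corpus = sample_corpus(
            grammar,
            config.n_sentences,
            seed=seeds["corpus"],
            max_len=config.max_len,
            word_class_map=word_classes,
        )
        corpus.save(outdir / "corpus.txt")
        done("corpus", t0)

        # -- language models ------------------------------------------------
        t0 = stage("models")
        ngram = train_ngram(corpus)
        srn = train_srn(
            corpus,
            SRNConfig(
                hidden=config.srn_hidden,
                epochs=config.srn_epochs,
                learning_rate=config.srn_learning_rate,
                seed=seeds["srn"],
            ),
        )
        series = {
            "Ngram": ngram_surprisal(ngram, corpus),
            "SRN": srn_surprisal(srn, corpus),
            "CFG": cfg_surprisal(grammar, corpus),
            "Null": null_surprisal(corpus),
        }
        V = len(corpus.tagset)
        reports = {k: accuracy_report(s, V) for k, s in series.items()}
        summary["accuracy"] = {
            k: {
                "mean_surprisal": r.mean_surprisal,
                "perplexity": r.perplexity,
                "bits_in_context": r.bits_in_context,
            }
            for k, r in reports.items()
        }
        comparisons = {}
        for a, b in (("Ngram", "CFG"), ("SRN", "CFG"), ("Ngram", "SRN")):
            t, df, p = compare_mean_surprisal(series[a], series[b])
            comparisons[f"{a}_vs_{b}"] = {"t": t, "df": df, "p": p}
        summary["surprisal_comparisons"] = comparisons
        surprisal_table(corpus, [series[m] for m in SURPRISAL_MODELS]).to_csv(
            outdir / "surprisal.tsv", sep="\t", index=False
        )
        done("models", t0)

        # -- EEG synthesis ---------------------------------------------------
        t0 = stage("epochs")
        montage = make_montage(config.n_electrodes, config.montage_k, seed=0)
        table = build_predictor_table(
            corpus, [series[m] for m in SURPRISAL_MODELS], seed=seeds["table"]
        )
        table.to_csv(outdir / "predictors.tsv", sep="\t", index=False)
        effects = []
        for ec in config.effects:
            spatial = spatial_pattern(montage, ec.pattern)
            x = table[ec.predictor].to_numpy(float)
            if ec.word_class is not None:
                x = x[table["word_class"] == ec.word_class]
            amp = effect_amplitude_for_snr(ec.snr, float(x.std()), config.noise_sd)
            effects.append(
                Effect(
                    predictor=ec.predictor,
                    spatial=spatial,
                    center=ec.center,
                    width=ec.width,
                    amplitude=amp,
                    word_class=ec.word_class,
                )
            )
        epochs = simulate_epochs(
            table,
            effects,
            montage,
            n_subjects=config.n_subjects,
            fs=config.fs,
            noise_sd=config.noise_sd,
            ar_coef=config.ar_coef,
            subject_gain_sd=config.subject_gain_sd,
            seed=seeds["epochs"],
        )
        epochs = lowpass_epochs(epochs, config.lowpass_hz)
        epochs = reject_trials(
            epochs, config.rejection_fraction, seed=seeds["reject"]
        )
        done("epochs", t0)

        # -- behavioral screening -------------------------------------------
        rule = behavioral_threshold(
            config.behavioral_questions,
            config.behavioral_choices,
            config.behavioral_alpha,
        )
        rng = np.random.default_rng(seeds["behavioral"])
        scores = rng.binomial(
            config.behavioral_questions,
            config.behavioral_accuracy,
            config.n_subjects,
        )
        flagged = [s for s in range(config.n_subjects) if not rule.passes(scores[s])]
        included = (
            list(range(config.n_subjects))
            if config.include_flagged_subjects
            else [s for s in range(config.n_subjects) if s not in flagged]
        )
        summary["behavioral"] = {
            "threshold": rule.threshold,
            "scores": [int(s) for s in scores],
            "flagged_subjects": flagged,
            "included_subjects": included,
        }

        # -- whole-head rERP + cluster tests --------------------------------
        t0 = stage("cluster")
        win = epochs.times >= 0.0
        cluster_results = {}
        cluster_summary = {}
        for model in SURPRISAL_MODELS:
            for wc in WORD_CLASSES:
                effect_name = f"{model}-{wc}"
                predictors = list(CONTROLS) + [f"surprisal_{model}"]
                targets, nulls = [], []
                for s in included:
                    design = build_design(
                        table, wc, predictors, mask=epochs.mask[s]
                    )
                    tb = fit_single_trial(epochs, design, s)
                    nb = fit_null(epochs, design, s, seed=seeds["null"] + s)
                    j = design.columns.index(f"surprisal_{model}")
                    targets.append(tb.beta[j][:, win])
                    nulls.append(nb.beta[j][:, win])
                result = permutation_test(
                    np.array(targets),
                    np.array(nulls),
                    montage,
                    n_perm=config.n_perm,
                    seed=seeds["cluster"],
                    alpha=config.cluster_alpha,
                    threshold=config.cluster_threshold,
                )
                tmap = paired_t_map(np.array(targets), np.array(nulls))
                cluster_results[effect_name] = (result, tmap)
                times_win = epochs.times[win]
                cluster_summary[effect_name] = [
                    {
                        "mass": c.mass,
                        "sign": c.sign,
                        "corrected_p": c.corrected_p,
                        "n_points": len(c.members),
                        "window_s": [
                            float(times_win[c.sample_range[0]]),
                            float(times_win[c.sample_range[1]]),
                        ],
                        "electrodes": sorted(c.electrodes),
                        "significant": c.corrected_p <= config.cluster_alpha,
                    }
                    for c in result.clusters[:5]
                ]
        summary["clusters"] = cluster_summary
        (outdir / "clusters.json").write_text(
            json.dumps(
                {"config_hash": chash, "clusters": cluster_summary},
                indent=1,
                default=_jsonable,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        done("cluster", t0)

        # -- ROI comparison ---------------------------------------------------
        if config.run_comparison:
            t0 = stage("compare")
            times_win = epochs.times[win]
            rois = define_rois(cluster_results, montage, times_win)
            summary["rois"] = [
                {
                    "id": r.id,
                    "electrodes": list(r.electrodes),
                    "window_s": list(r.window),
                    "source": r.source_effect,
                    "sign": r.sign,
                }
                for r in rois
            ]
            if rois:
                sub_epochs = EpochSet(
                    data=epochs.data[included],
                    times=epochs.times,
                    fs=epochs.fs,
                    montage=montage,
                    mask=epochs.mask[included],
                )
                roi_data = {r.id: extract_roi(sub_epochs, r, table) for r in rois}
                ledger = stepwise_compare(
                    roi_data,
                    seed=seeds["sampler"],
                    config=GibbsConfig(
                        chains=config.chains,
                        warmup=config.warmup,
                        draws=config.draws,
                    ),
                )
                ledger.to_tsv(outdir / "ledger.tsv")
                summary["ledger"] = ledger.rows.to_dict(orient="records")
            else:
                summary["ledger"] = []
            done("compare", t0)

        summary_text = json.dumps(
            summary, indent=1, sort_keys=True, default=_jsonable
        )
        (outdir / "summary.json").write_text(summary_text, encoding="utf-8")
        return summary
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
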