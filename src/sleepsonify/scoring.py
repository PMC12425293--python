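"""Staging-performance statistics: agreement, accuracy, RT filters, tests.

The central quantity is Cohen's kappa, chance-corrected agreement between
a rater's stages and the reference stages of a block,

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement fraction and p_e the agreement expected
from the marginal label frequencies.  Kappa is undefined (a typed None,
never a silent zero) when every epoch in the block truly has the same
stage.  Supporting machinery: per-stage percent correct, a +/-2-sigma
reaction-time outlier filter, a correct-trials-only filter, the practice
bot gate (median RT < 2 s fails), a paired Wilcoxon signed-rank / sign-
flip-permutation comparison, and stratification of participants by
staging experience.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .eeg_io import STAGES, validate_stage

logger = logging.getLogger(__name__)

#: Experience bins: self-reported polysomnograms staged in the past year.
EXPERIENCE_BINS = ("1-10", "11-20", "21-40", "41-80", ">80")

BLOCK_IDS = ("sound", "no_sound", "practice")


class Trial(NamedTuple):
    epoch_index: int
    true_stage: str
    response: str
    rt: float  # seconds


@dataclass
class ResponseSet:
    """Per-trial responses of one rater on one block."""

    trials: list[Trial]
    block_id: str = "sound"
    participant_id: str = "anon"

    def __post_init__(self) -> None:
        for t in self.trials:
            validate_stage(t.true_stage)
            validate_stage(t.response)
            if t.rt <= 0:
                raise ValueError(f"non-positive reaction time {t.rt} in trial {t}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_correct(self) -> int:
        return sum(t.response == t.true_stage for t in self.trials)

    @property
    def truths(self) -> list[str]:
        return [t.true_stage for t in self.trials]

    @property
    def responses(self) -> list[str]:
        return [t.response for t in self.trials]

    @property
    def rts(self) -> np.ndarray:
        return np.array([t.rt for t in self.trials], dtype=float)


@dataclass
class ScoreReport:
    """Evaluation summary of one response block."""

    kappa: float | None
    per_stage_accuracy: dict[str, float]  # percent
    confusion: np.ndarray  # 5x5 counts, rows = true stage
    n_trials: int
    n_correct: int
    rt_summary: dict[str, float]  # mean / median / sd of included RTs

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "per_stage_accuracy": self.per_stage_accuracy,
            "confusion": {
                "labels": list(STAGES),
                "counts": self.confusion.astype(int).tolist(),
            },
            "n_trials": self.n_trials,
            "n_correct": self.n_correct,
            "rt_summary": self.rt_summary,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class ParticipantRecord:
    """One participant: experience level plus their response blocks."""

    participant_id: str
    experience_bin: str
    blocks: dict[str, ResponseSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experience_bin not in EXPERIENCE_BINS:
            raise ValueError(
                f"experience_bin {self.experience_bin!r} not in {EXPERIENCE_BINS}"
            )


# ---------------------------------------------------------------------------
# core statistics


def confusion_matrix(responses: ResponseSet) -> np.ndarray:
    """5x5 count matrix, rows = true stage, columns = issued stage."""
    m = np.zeros((5, 5), dtype=int)
    for t in responses.trials:
        m[STAGES.index(t.true_stage), STAGES.index(t.response)] += 1
    return m


def cohens_kappa(responses: ResponseSet) -> float | None:
    """Chance-corrected agreement between issued and true stages.

    Returns None (undefined) when every epoch truly has the same stage, or
    when the chance-agreement term p_e equals 1.
    """
    n = responses.n_trials
    if n == 0:
        raise ValueError("cannot compute kappa on an empty response set")
    if len(set(responses.truths)) == 1:
        return None
    m = confusion_matrix(responses)
    p_o = np.trace(m) / n
    p_e = float(np.sum(m.sum(axis=1) * m.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def per_stage_accuracy(responses: ResponseSet) -> dict[str, float]:
    """Percent of true-stage-X epochs identified as X, per present stage.

    Stages with no true instance in the block are omitted from the map.
    E.g. recognising 5 of 10 true Wake epochs gives Wake accuracy 50.0.
    """
    out: dict[str, float] = {}
    m = confusion_matrix(responses)
    for i, stage in enumerate(STAGES):
        n_true = m[i].sum()
        if n_true > 0:
            out[stage] = 100.0 * m[i, i] / n_true
    return out


def rt_summary(responses: ResponseSet) -> dict[str, float]:
    """Mean / median / population SD of the set's reaction times."""
    rts = responses.rts
    if len(rts) == 0:
        return {"mean": float("nan"), "median": float("nan"), "sd": float("nan"),
                "n": 0}
    return {
        "mean": float(np.mean(rts)),
        "median": float(np.median(rts)),
        "sd": float(np.std(rts)),
        "n": int(len(rts)),
    }


# ---------------------------------------------------------------------------
# trial filters


def filter_rt_outliers(responses: ResponseSet, k: float = 2.0) -> ResponseSet:
    """Drop trials whose RT lies more than ``k`` sigma from the mean.

    Mean and (population) sigma are computed once on the unfiltered set;
    the bound is |rt - mean| <= k*sigma, so identical RTs (sigma = 0) all
    survive at equality.  Trial order is preserved.
    """
    if responses.n_trials < 2:
        warnings.warn("fewer than 2 trials: RT filter returns input unchanged")
        return ResponseSet(list(responses.trials), responses.block_id,
                           responses.participant_id)
    rts = responses.rts
    mean, sd = float(np.mean(rts)), float(np.std(rts))
    kept = [t for t in responses.trials if abs(t.rt - mean) <= k * sd]
    return ResponseSet(kept, responses.block_id, responses.participant_id)


def correct_only(responses: ResponseSet) -> ResponseSet:
    """Keep only trials where the issued stage matches the true stage."""
    kept = [t for t in responses.trials if t.response == t.true_stage]
    return ResponseSet(kept, responses.block_id, responses.participant_id)


def practice_gate(practice: ResponseSet, threshold: float = 2.0) -> bool:
    """Bot/inattention gate: True (pass) unless median RT < threshold.

    The inequality is strict: a median of exactly ``threshold`` passes.
    """
    if practice.n_trials == 0:
        raise ValueError("practice gate needs a non-empty response set")
    return not float(np.median(practice.rts)) < threshold


# ---------------------------------------------------------------------------
# paired comparison and stratification


class PairedResult(NamedTuple):
    p_value: float
    direction: str  # "a>b", "b>a", or "equal" (by median difference)
    n_nonzero: int  # pairs remaining after dropping zero differences


def paired_compare(values_a: Iterable[float], values_b: Iterable[float],
                   method: str = "signed_rank_exact",
                   n_permutations: int = 10_000,
                   seed: int | None = None) -> PairedResult:
    """Two-sided paired comparison of per-participant metrics.

    ``signed_rank_exact`` uses the exact Wilcoxon signed-rank null
    (enumeration of all sign assignments) for n <= 25, falling back to a
    sign-flip permutation beyond that; ``permutation`` always uses a
    seeded sign-flip permutation of the mean difference with
    ``n_permutations`` draws.  Zero differences are dropped before
    ranking, per the original signed-rank convention.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_compare needs two equal-length vectors, n >= 2")
    d = a - b
    med = float(np.median(d))
    direction = "a>b" if med > 0 else ("b>a" if med < 0 else "equal")
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return PairedResult(1.0, "equal", 0)

    if method == "signed_rank_exact":
        mode = "exact" if len(nz) <= 25 else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method=mode)
        return PairedResult(float(res.pvalue), direction, len(nz))
    if method == "permutation":
        # sign-flip permutation of the signed-rank statistic, so the null
        # approximates the exact Wilcoxon distribution
        rng = np.random.default_rng(seed)
        ranks = stats.rankdata(np.abs(nz))
        center = ranks.sum() / 2.0
        observed = abs(float(ranks[nz > 0].sum()) - center)
        flips = rng.random((n_permutations, len(nz))) < 0.5
        null = np.abs(flips @ ranks - center)
        p = (1 + np.sum(null >= observed - 1e-12)) / (n_permutations + 1)
        return PairedResult(float(p), direction, len(nz))
    raise ValueError(f"unknown method {method!r}")


def stratify_by_experience(
    records: Iterable[ParticipantRecord],
    block_a: str = "sound",
    block_b: str = "no_sound",
) -> dict[str, pd.DataFrame]:
    """Per-experience-bin tables of paired (sound, no-sound) kappas.

    Each returned DataFrame has columns ``participant_id``,
    ``kappa_<block_a>``, ``kappa_<block_b>`` ready for
    :func:`paired_compare`.  Empty bins are omitted with a log notice;
    participants missing either block are skipped.
    """
    rows: dict[str, list] = {b: [] for b in EXPERIENCE_BINS}
    for rec in records:
        if block_a not in rec.blocks or block_b not in rec.blocks:
            logger.info("participant %s lacks block(s); skipped", rec.participant_id)
            continue
        ka = cohens_kappa(rec.blocks[block_a])
        kb = cohens_kappa(rec.blocks[block_b])
        if ka is None or kb is None:
            logger.info("participant %s has undefined kappa; skipped",
                        rec.participant_id)
            continue
        rows[rec.experience_bin].append((rec.participant_id, ka, kb))
    out = {}
    for bin_name in EXPERIENCE_BINS:
        if not rows[bin_name]:
            logger.info("experience bin %s is empty; omitted", bin_name)
            continue
        out[bin_name] = pd.DataFrame(
            rows[bin_name],
            columns=["participant_id", f"kappa_{block_a}", f"kappa_{block_b}"],
        )
    return out


# ---------------------------------------------------------------------------
# report assembly and table I/O

RESPONSE_COLUMNS = ["participant_id", "block", "epoch", "true_stage",
                    "response", "rt_seconds"]


def score_report(responses: ResponseSet, rt_sigma: float = 2.0) -> ScoreReport:
    """Full evaluation of one block.

    Accuracy statistics use all trials; the RT summary follows the
    reporting convention of staging experiments — correct trials only,
    after the +/-``rt_sigma`` outlier exclusion.
    """
    rt_set = correct_only(responses)
    if rt_set.n_trials >= 2:
        rt_set = filter_rt_outliers(rt_set, k=rt_sigma)
    return ScoreReport(
        kappa=cohens_kappa(responses),
        per_stage_accuracy=per_stage_accuracy(responses),
        confusion=confusion_matrix(responses),
        n_trials=responses.n_trials,
        n_correct=responses.n_correct,
        rt_summary=rt_summary(rt_set),
    )


def responses_to_frame(sets: Iterable[ResponseSet]) -> pd.DataFrame:
    rows = []
    for rs in sets:
        for t in rs.trials:
            rows.append((rs.participant_id, rs.block_id, t.epoch_index,
                         t.true_stage, t.response, t.rt))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def write_responses(sets: Iterable[ResponseSet], path: str | Path) -> None:
    responses_to_frame(sets).to_csv(path, index=False)


def read_responses(path: str | Path) -> list[ResponseSet]:
    """Read a response CSV back into one ResponseSet per participant-block."""
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for (pid, block), grp in df.groupby(["participant_id", "block"], sort=False):
        trials = [Trial(int(r.epoch), str(r.true_stage), str(r.response),
                        float(r.rt_seconds))
                  for r in grp.itertuples()]
        out.append(ResponseSet(trials, block_id=str(block),
                               participant_id=str(pid)))
    return out
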