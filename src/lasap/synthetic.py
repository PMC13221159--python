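"""Synthetic cohorts and waveforms with the statistical structure the
pipeline assumes.

The cohort generator emulates a caregiver-interview study: per-participant
keyword counts over a keyword/topic lexicon, a high-dimensional acoustic
block partially explained by the linguistic block, and a latent stress
score mapped to a bounded Caregiver Burden Inventory (CBI) scale and
thresholded into a binary high/low stress label.  The stress-informative
acoustic component is constructed orthogonal to the linguistic loading, so
residualizing the acoustic block on the linguistic block provably retains
the acoustic-only signal.

The waveform generator produces periodic signals whose per-cycle peak
amplitudes vary with controlled relative dispersion — the low/high shimmer
contrast used to exercise the built-in acoustic extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .acoustic import Waveform
from .blocks import BlockSet, FeatureBlock
from .linguistic import KeywordLexicon

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_waveform",
    "assign_label",
    "write_cohort",
    "read_cohort",
]

CBI_MAX = 96  # 24 items x max score 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference study: 100 participants, 53 keywords
    over 14 topics, 6503 acoustic features, CBI threshold 36 with a 56%
    high-stress prevalence.  ``cross_loading`` is the fraction of acoustic
    variance explained by the linguistic block; ``ling_effect`` the
    standardized class shift of keyword log-rates; ``acou_effect`` the
    class shift of the acoustic-only component relative to its residual
    SD, so the planted signal survives orthogonalization.
    """

    n_participants: int = 100
    n_keywords: int = 53
    n_topics: int = 14
    n_acoustic: int = 6503
    cross_loading: float = 0.8
    ling_effect: float = 1.0
    acou_effect: float = 0.8
    noise_sd: float = 1.0
    cbi_threshold: int = 36
    prevalence_high: float = 0.56
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_keywords", "n_topics", "n_acoustic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.cross_loading <= 1.0:
            raise ValueError("cross_loading must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.cbi_threshold <= CBI_MAX:
            raise ValueError(f"cbi_threshold must be within [0, {CBI_MAX}]")
        if not 0.0 < self.prevalence_high < 1.0:
            raise ValueError("prevalence_high must be in (0, 1)")


@dataclass
class SyntheticCohort:
    """Labeled cohort: paired feature blocks, CBI scores and labels."""

    linguistic: FeatureBlock
    acoustic: FeatureBlock
    cbi_score: np.ndarray
    label: np.ndarray
    lexicon: KeywordLexicon
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        self.cbi_score = np.asarray(self.cbi_score, dtype=int)
        self.label = np.asarray(self.label, dtype=int)
        n = self.linguistic.n_participants
        if not (self.acoustic.n_participants == len(self.cbi_score) == len(self.label) == n):
            raise ValueError("cohort components disagree on participant count")
        if self.config is not None:
            expected = (self.cbi_score > self.config.cbi_threshold).astype(int)
            if not np.array_equal(expected, self.label):
                raise ValueError("labels inconsistent with CBI threshold")

    @property
    def blocks(self) -> BlockSet:
        return BlockSet(self.linguistic, self.acoustic)


def assign_label(cbi_score: float, threshold: int = 36) -> int:
    """1 (high stress) iff the CBI total exceeds the threshold.

    A score of exactly the threshold is low stress: totals of 36 or lower
    indicate low stress, above 36 high stress.
    """
    if not 0 <= cbi_score <= CBI_MAX:
        raise ValueError(f"CBI score {cbi_score} outside [0, {CBI_MAX}]")
    return int(cbi_score > threshold)


def _round_robin_lexicon(n_keywords: int, n_topics: int) -> KeywordLexicon:
    # Topic membership assigned round-robin; the real keyword->topic map is
    # study-specific configuration, not something the generator can know.
    entries = {f"kw{j:02d}": f"topic{j % n_topics:02d}" for j in range(n_keywords)}
    processes = ("belief_systems", "organizational_patterns", "communication_patterns")
    topic_process = {f"topic{t:02d}": processes[t % 3] for t in range(n_topics)}
    return KeywordLexicon(entries, topic_process)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one labeled cohort; byte-identical under the same config.

    Construction:

    1. latent stress ``z ~ N(Phi^-1(prevalence), 1)`` mapped to an integer
       CBI total ``clip(round(threshold + 0.5 + 12 z), 0, 96)`` and
       thresholded into the binary label;
    2. keyword counts ``Poisson(exp(b_j + (ling_effect/2) g_j s_i))`` with
       per-keyword base rates, a unit-norm loading vector ``g`` and class
       sign ``s_i = +/-1``;
    3. acoustic rows ``sqrt(c) * shared + delta * s_i * v / 2 + sqrt(1-c) *
       noise_sd * eps`` where ``shared`` is a standardized linear map of
       the standardized keyword counts, ``v`` is a unit direction
       orthogonal to that map's row space, and ``delta = acou_effect *
       sqrt(1-c) * noise_sd`` plants a class shift of ``acou_effect``
       residual SDs along ``v``.

    The cross-loading map is projected off the population discriminative
    direction of the keyword block, so the shared component replicates
    linguistic *nuisance* variation rather than duplicating the class
    signal: redundant overlapping information that inflates the fused
    feature space without adding predictive value.  Fusing without
    residualization therefore buries both signals under correlated
    nuisance, while residualization removes the shared component and
    exposes the acoustic-only signal along ``v`` — the regime in which
    orthogonalized fusion beats raw fusion and either block alone loses
    to the fused, processed representation.
    """
    rng = np.random.default_rng(config.seed)
    n, p_kw, p_ac = config.n_participants, config.n_keywords, config.n_acoustic

    # --- latent stress, CBI scale, label -------------------------------
    z = rng.standard_normal(n) + norm.ppf(config.prevalence_high)
    cbi = np.clip(np.round(config.cbi_threshold + 0.5 + 12.0 * z), 0, CBI_MAX).astype(int)
    label = (cbi > config.cbi_threshold).astype(int)
    sign = 2.0 * label - 1.0

    # --- linguistic block: class-shifted Poisson keyword counts --------
    base_log_rate = rng.uniform(np.log(0.5), np.log(5.0), size=p_kw)
    g = rng.standard_normal(p_kw)
    g /= np.linalg.norm(g)
    log_rate = base_log_rate[None, :] + (config.ling_effect / 2.0) * np.outer(sign, g)
    counts = rng.poisson(np.exp(log_rate)).astype(float)

    # --- acoustic block ------------------------------------------------
    sd = counts.std(axis=0)
    sd[sd < 1e-12] = 1.0
    L_std = (counts - counts.mean(axis=0)) / sd
    W = rng.standard_normal((p_kw, p_ac))
    # first-order class-shift direction in standardized count space:
    # mean shift ~ rate * ling_effect * g, SD ~ sqrt(rate)
    d = config.ling_effect * g * np.sqrt(np.exp(base_log_rate))
    d_norm = np.linalg.norm(d)
    if d_norm > 1e-12:
        d /= d_norm
        W -= np.outer(d, d @ W)
    shared = L_std @ W
    s_sd = shared.std(axis=0)
    s_sd[s_sd < 1e-12] = 1.0
    shared /= s_sd

    v = rng.standard_normal(p_ac)
    if p_ac > p_kw:  # project v off the linguistic map's row space
        q, _ = np.linalg.qr(W.T)
        v = v - q @ (q.T @ v)
    v /= np.linalg.norm(v)

    c = config.cross_loading
    delta = config.acou_effect * np.sqrt(1.0 - c) * config.noise_sd
    acoustic = (
        np.sqrt(c) * shared
        + (delta / 2.0) * np.outer(sign, v)
        + np.sqrt(1.0 - c) * config.noise_sd * rng.standard_normal((n, p_ac))
    )

    ids = [f"P{i:04d}" for i in range(n)]
    lexicon = _round_robin_lexicon(p_kw, config.n_topics)
    ling_block = FeatureBlock(counts, list(lexicon.entries), ids, "linguistic")
    acou_block = FeatureBlock(acoustic, [f"ac{j:04d}" for j in range(p_ac)], ids, "acoustic")
    return SyntheticCohort(ling_block, acou_block, cbi, label, lexicon, config)


def generate_waveform(
    n_cycles: int,
    base_amplitude: float = 1.0,
    shimmer_level: float = 0.0,
    cycle_length: int = 64,
    seed: int = 0,
    rate: int = 16000,
) -> Waveform:
    """Periodic signal with controlled per-cycle amplitude dispersion.

    Each cycle is one sine period scaled by ``base_amplitude * (1 +
    shimmer_level * u)`` with ``u ~ N(0, 1)`` truncated to [-3, 3], so the
    relative dispersion (CV) of the peak amplitudes is ~``shimmer_level``
    and ``shimmer_level = 0`` gives exactly constant peaks.
    """
    if n_cycles < 2:
        raise ValueError("shimmer is undefined on fewer than 2 cycles")
    if cycle_length < 8:
        raise ValueError("cycle_length must be >= 8 samples")
    if shimmer_level < 0:
        raise ValueError("shimmer_level must be >= 0")
    rng = np.random.default_rng(seed)
    u = np.clip(rng.standard_normal(n_cycles), -3.0, 3.0)
    amplitudes = base_amplitude * (1.0 + shimmer_level * u)
    amplitudes = np.maximum(amplitudes, 0.05 * base_amplitude)
    one_cycle = np.sin(2.0 * np.pi * np.arange(cycle_length) / cycle_length)
    samples = np.concatenate([a * one_cycle for a in amplitudes])
    return Waveform(samples, rate, peak_amplitudes=amplitudes)


# ---------------------------------------------------------------------------
# Cohort persistence: one CSV per block, TSV labels, YAML lexicon.


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.linguistic.write_csv(d / "linguistic.csv")
    cohort.acoustic.write_csv(d / "acoustic.csv")
    labels = pd.DataFrame(
        {"id": cohort.linguistic.participant_ids, "cbi_score": cohort.cbi_score, "label": cohort.label}
    )
    labels.to_csv(d / "labels.tsv", sep="\t", index=False)
    cohort.lexicon.to_yaml(d / "lexicon.yaml")


def read_cohort(directory) -> SyntheticCohort:
    d = Path(directory)
    ling = FeatureBlock.read_csv(d / "linguistic.csv", "linguistic")
    acou = FeatureBlock.read_csv(d / "acoustic.csv", "acoustic")
    labels = pd.read_csv(d / "labels.tsv", sep="\t")
    lexicon = KeywordLexicon.from_yaml(d / "lexicon.yaml")
    return SyntheticCohort(
        ling, acou, labels["cbi_score"].to_numpy(), labels["label"].to_numpy(), lexicon
    )
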