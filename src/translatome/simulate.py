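"""Synthetic polysome-profiling data with known ground truth.

Emulates the quantities the pipeline consumes in a real study — per
transcript x sample posterior summaries of log expression, a factorial
sample design, and 5'UTR sequence sets — so every downstream stage can
be tested end to end without raw sequencing data.

Expression model (natural-log scale), per transcript t and sample i:

    mu_ti = baseline_t + cond_t * [knockdown] + frac_t * [polysomal]
            + delta_t * [knockdown & polysomal]
    y_ti  = mu_ti + Normal(0, sigma_bio) + Normal(0, s_ti)

where ``s_ti`` (drawn uniformly from ``meas_sd_range``) plays the role
of the quantifier's posterior SD and is reported exactly alongside
``y_ti``; the downstream model treats it as known measurement SD.  A
fraction ``frac_interaction`` of transcripts carries a true interaction
``delta_t = +/- delta_scale`` (random sign); the rest have
``delta_t = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from translatome.design import SampleDesign
from translatome.utr import normalize_sequence

__all__ = ["SimConfig", "UTRSimSpec", "simulate_expression", "simulate_utrs"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the expression simulator.

    Defaults mirror a quadruplicate knockdown-vs-control polysome
    profiling experiment with a minority of transcripts (20%) carrying a
    strong translational shift (|delta| = 2 natural-log units) against
    small replicate noise.
    """

    n_transcripts: int = 1000
    frac_interaction: float = 0.2
    delta_scale: float = 2.0
    baseline_range: tuple[float, float] = (2.0, 10.0)
    cond_effect_sd: float = 0.25
    frac_effect_sd: float = 0.5
    sigma_bio: float = 0.1
    meas_sd_range: tuple[float, float] = (0.05, 0.2)
    n_replicates: int = 4
    include_total: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.n_replicates < 2:
            raise ValueError("need n_transcripts > 0 and n_replicates >= 2")
        if not 0.0 <= self.frac_interaction <= 1.0:
            raise ValueError("frac_interaction must lie in [0, 1]")
        for name in ("delta_scale", "cond_effect_sd", "frac_effect_sd", "sigma_bio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.meas_sd_range
        if not 0 < lo <= hi:
            raise ValueError("meas_sd_range must satisfy 0 < lo <= hi")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ValueError("baseline_range must be ordered")


def _transcript_rng(seed: int, index: int) -> np.random.Generator:
    # per-transcript substream: reproducible independently of iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Simulate a posterior-summary matrix with known interaction truth.

    Returns
    -------
    expression:
        Tidy DataFrame (transcript_id, sample_id, mean_log_expr,
        sd_log_expr): 16 subpolysomal/polysomal samples per transcript
        (2 conditions x 2 fractions x n_replicates), plus 8 total-mRNA
        samples when ``include_total`` is set.
    design:
        Matching :class:`~translatome.design.SampleDesign`.
    truth:
        DataFrame (transcript_id, true_delta, true_class) with
        ``true_class`` = ``dependent`` iff delta < 0, ``independent``
        iff delta > 0, ``null`` iff delta == 0.
    """
    fractions = ("subpolysomal", "polysomal") + (
        ("total",) if config.include_total else ()
    )
    design = SampleDesign.balanced(config.n_replicates, fractions)
    t = design.table
    kd = (t["condition"] == "knockdown").to_numpy(float)
    poly = (t["fraction"] == "polysomal").to_numpy(float)
    inter = kd * poly
    n_samp = len(t)

    width = len(str(config.n_transcripts - 1))
    records = []
    truth_rows = []
    for j in range(config.n_transcripts):
        rng = _transcript_rng(config.seed, j)
        tid = f"TX{j:0{width}d}"
        baseline = rng.uniform(*config.baseline_range)
        cond_eff = rng.normal(0.0, config.cond_effect_sd)
        frac_eff = rng.normal(0.0, config.frac_effect_sd)
        has_effect = rng.uniform() < config.frac_interaction
        if has_effect:
            delta = config.delta_scale * (1.0 if rng.uniform() < 0.5 else -1.0)
        else:
            delta = 0.0
        mu = baseline + cond_eff * kd + frac_eff * poly + delta * inter
        s = rng.uniform(*config.meas_sd_range, size=n_samp)
        y = mu + rng.normal(0.0, config.sigma_bio, size=n_samp) + rng.normal(
            0.0, 1.0, size=n_samp
        ) * s
        records.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "sample_id": t["sample_id"].to_numpy(),
                    "mean_log_expr": y,
                    "sd_log_expr": s,
                }
            )
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "true_delta": delta,
                "true_class": (
                    "null" if delta == 0 else ("dependent" if delta < 0 else "independent")
                ),
            }
        )
    expression = pd.concat(records, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return expression, design, truth


@dataclass(frozen=True)
class UTRSimSpec:
    """Configuration of the 5'UTR sequence simulator.

    Sequences are iid draws with base probabilities set by
    ``gc_target`` (G and C each at gc/2); lengths are log-normal with
    the given median and log-SD, clipped to ``length_bounds`` —
    a shape typical of human 5'UTRs.  Each pattern in
    ``planted_motifs`` is a literal sequence overwritten at a uniformly
    random position with the stated probability.
    """

    n_sequences: int = 100
    length_median: float = 150.0
    length_log_sd: float = 0.6
    length_bounds: tuple[int, int] = (20, 3000)
    gc_target: float = 0.6
    planted_motifs: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must lie strictly between 0 and 1")
        if self.length_median <= 0 or self.length_log_sd < 0:
            raise ValueError("invalid length distribution")
        if not 0 < self.length_bounds[0] <= self.length_bounds[1]:
            raise ValueError("length_bounds must be ordered and positive")
        for pattern, prob in self.planted_motifs:
            normalize_sequence(pattern)  # raises on non-nucleotide patterns
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"plant probability out of [0, 1]: {prob}")


def simulate_utrs(spec: UTRSimSpec) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate 5'UTR sequences with planted-motif ground truth.

    Returns
    -------
    records:
        List of ``(transcript_id, gene_id, sequence)`` triples,
        FASTA-writable; one gene per transcript by default.
    truth:
        DataFrame with ``transcript_id``, ``length`` and one boolean
        ``planted:<pattern>`` column per planted motif.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    gc = spec.gc_target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    width = len(str(spec.n_sequences - 1))
    records = []
    truth_rows = []
    for j in range(spec.n_sequences):
        length = int(
            np.clip(
                np.round(rng.lognormal(np.log(spec.length_median), spec.length_log_sd)),
                *spec.length_bounds,
            )
        )
        seq = rng.choice(bases, size=length, p=probs)
        row: dict[str, object] = {"transcript_id": f"UTX{j:0{width}d}"}
        for pattern, prob in spec.planted_motifs:
            motif = normalize_sequence(pattern)
            if len(motif) > length:
                raise ValueError(
                    f"cannot plant {len(motif)}-nt motif in {length}-nt sequence"
                )
            planted = bool(rng.uniform() < prob)
            if planted:
                start = int(rng.integers(0, length - len(motif) + 1))
                seq[start : start + len(motif)] = list(motif)
            row[f"planted:{pattern}"] = planted
        row["length"] = length
        tid = row["transcript_id"]
        records.append((tid, f"UG{j:0{width}d}", "".join(seq)))
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)
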