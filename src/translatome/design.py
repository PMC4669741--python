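"""Sample designs and design-matrix pairs for nested model comparison.

A polysome-profiling experiment measures each transcript in samples laid
out on a factorial grid: condition (control vs knockdown siRNA) crossed
with sucrose-gradient fraction (total, subpolysomal, polysomal), with
replicates per cell.  Two nested regression designs are built from such
a layout:

* DE ("differential expression"): intercept-only vs intercept +
  condition, on the 8 samples of a single fraction.
* DoD ("difference of differences"): additive condition + fraction model
  vs the same model plus a condition x fraction interaction, on the 16
  subpolysomal/polysomal samples.  The interaction coefficient is the
  change, upon knockdown, of the polysomal-vs-subpolysomal log-ratio —
  the translational shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "knockdown")
FRACTIONS = ("total", "subpolysomal", "polysomal")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered sample layout: one row per sample.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, ``condition``
        (``control``/``knockdown``), ``fraction``
        (``total``/``subpolysomal``/``polysomal``) and ``replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        bad_frac = set(self.table["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValueError(f"unknown fractions: {sorted(bad_frac)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, fractions: tuple[str, ...]) -> "SampleDesign":
        sub = self.table[self.table["fraction"].isin(fractions)].reset_index(drop=True)
        return SampleDesign(sub)

    @classmethod
    def balanced(
        cls,
        n_replicates: int = 4,
        fractions: tuple[str, ...] = ("subpolysomal", "polysomal"),
    ) -> "SampleDesign":
        """Standard balanced layout: every condition x fraction cell has
        ``n_replicates`` samples, ids ``<condition>_<fraction>_r<i>``."""
        rows = []
        for frac in fractions:
            for cond in CONDITIONS:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{cond}_{frac}_r{rep}",
                            "condition": cond,
                            "fraction": frac,
                            "replicate": rep,
                        }
                    )
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class DesignPair:
    """A nested pair of design matrices for Bayesian model comparison.

    ``X0`` is the simple model, ``X1`` the complex one; the column space
    of ``X0`` is contained in that of ``X1`` and ``X1`` has full column
    rank.  ``delta_column`` is the index (into ``X1``'s columns) of the
    coefficient whose inclusion distinguishes the two models.
    """

    X0: np.ndarray
    X1: np.ndarray
    name: str
    delta_column: int
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.X0.shape[0] != self.X1.shape[0]:
            raise ValueError("X0 and X1 must have the same number of rows")
        if np.linalg.matrix_rank(self.X1) < self.X1.shape[1]:
            raise ValueError("X1 is rank-deficient")
        # nesting: residual of projecting X0 onto col(X1) must vanish
        proj, *_ = np.linalg.lstsq(self.X1, self.X0, rcond=None)
        if not np.allclose(self.X1 @ proj, self.X0, atol=1e-8):
            raise ValueError("X0 columns are not in the column space of X1")


def _check_balance(table: pd.DataFrame, keys: list[str]) -> None:
    counts = table.groupby(keys, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            f"unbalanced design: replicate counts per {'/'.join(keys)} cell are "
            f"{counts.to_dict()}"
        )


def build_design_de(design: SampleDesign) -> DesignPair:
    """Nested pair for condition-only differential expression.

    Expects the 8 samples of one fraction, both conditions, balanced.
    ``X0`` is the intercept-only model; ``X1`` adds a knockdown
    indicator.
    """
    t = design.table
    fractions = set(t["fraction"])
    if len(fractions) != 1:
        raise ValueError(f"DE design needs a single fraction, got {sorted(fractions)}")
    if set(t["condition"]) != set(CONDITIONS):
        raise ValueError("DE design needs both conditions")
    _check_balance(t, ["condition"])
    n = len(t)
    kd = (t["condition"] == "knockdown").to_numpy(float)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), kd])
    return DesignPair(X0, X1, "DE", delta_column=1, sample_ids=tuple(t["sample_id"]))


def build_design_dod(design: SampleDesign) -> DesignPair:
    """Nested pair for the difference-of-differences (interaction) test.

    Expects the 16 samples covering both conditions crossed with the
    subpolysomal and polysomal fractions, balanced.  ``X0`` models
    additive condition and fraction effects; ``X1`` adds an interaction
    column that is 1 exactly for (knockdown, polysomal) samples, so the
    interaction coefficient delta equals
    ``(poly_KD - poly_ctrl) - (subpoly_KD - subpoly_ctrl)``.
    """
    t = design.table
    wanted = {"subpolysomal", "polysomal"}
    if set(t["fraction"]) != wanted:
        raise ValueError(
            "DoD design needs exactly the subpolysomal and polysomal fractions, "
            f"got {sorted(set(t['fraction']))}"
        )
    cells = set(zip(t["condition"], t["fraction"]))
    expected = {(c, f) for c in CONDITIONS for f in wanted}
    if cells != expected:
        raise ValueError(f"DoD design missing cells: {sorted(expected - cells)}")
    _check_balance(t, ["condition", "fraction"])
    n = len(t)
    kd = (t["condition"] == "knockdown").to_numpy(float)
    poly = (t["fraction"] == "polysomal").to_numpy(float)
    X0 = np.column_stack([np.ones(n), kd, poly])
    X1 = np.column_stack([np.ones(n), kd, poly, kd * poly])
    return DesignPair(X0, X1, "DoD", delta_column=3, sample_ids=tuple(t["sample_id"]))
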