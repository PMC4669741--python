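"""5'UTR sequence features and motif/structure scanners.

Features computed per UTR: G/C content, length, predicted minimum free
energy of secondary structure (via a pluggable folding engine), upstream
AUG count, and presence flags for a set of structure-prone motifs:

* G-quadruplex potential: ``GG N{1,7} GG N{1,7} GG N{1,7} GG`` or the
  GGG-tract analogue — four G-tracts separated by loops of 1-7
  nucleotides.
* Paired GGAGG element: ``GGAGG N{4,10} GGAGG`` — two GGAGG motifs
  joined by a short linker, with higher-order (hexad/tetrad) folding
  potential.
* Arbitrary IUPAC motifs with bounded repeat counts, e.g. the GGC-repeat
  motif ``GC(GGC){3}G``, the G/A-rich consensus ``GGAGG`` and a
  configurable U-run ``U{6,}``.

Sequences may be RNA or DNA in either case; everything is matched on the
uppercase DNA alphabet (U normalized to T).
"""

from __future__ import annotations

import logging
import re
import subprocess
from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# default motif patterns (IUPAC grammar, see scan_motif)
GC_RICH_MOTIF = "GC(GGC){3}G"
GA_RICH_MOTIF = "GGAGG"
U_RICH_MOTIF = "U{6,}"

_VALID = set("ACGTN")

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGTN]",
}

_G4_RE = re.compile(
    r"GG[ACGTN]{1,7}GG[ACGTN]{1,7}GG[ACGTN]{1,7}GG"
    r"|GGG[ACGTN]{1,7}GGG[ACGTN]{1,7}GGG[ACGTN]{1,7}GGG"
)
_PAIRED_GGAGG_RE = re.compile(r"GGAGG[ACGTN]{4,10}GGAGG")


def normalize_sequence(seq: str) -> str:
    """Uppercase, RNA->DNA normalized copy of ``seq``.

    Raises ``ValueError`` for empty input or characters outside
    A/C/G/T/U/N.
    """
    if not seq:
        raise ValueError("empty sequence")
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return norm


@dataclass(frozen=True)
class UTRRecord:
    """One 5'UTR sequence with its transcript and gene ids."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def gc_content(seq: str) -> float:
    """Fraction of G+C among unambiguous bases; NaN if all bases are N."""
    norm = normalize_sequence(seq)
    counts = {b: norm.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / total


def count_uaugs(seq: str) -> int:
    """Number of ATG/AUG occurrences, frame-agnostic, overlaps counted."""
    norm = normalize_sequence(seq)
    return sum(1 for _ in re.finditer(r"(?=ATG)", norm))


def scan_g4(seq: str, with_intervals: bool = False):
    """G-quadruplex-forming potential.

    True iff the sequence contains four GG tracts (or four GGG tracts)
    separated by loops of 1-7 arbitrary nucleotides.  With
    ``with_intervals`` also returns the leftmost non-overlapping,
    shortest-loop-first match intervals as ``(start, end)`` pairs.
    """
    norm = normalize_sequence(seq)
    if not with_intervals:
        return _G4_RE.search(norm) is not None
    intervals: list[tuple[int, int]] = []
    pos = 0
    while pos <= len(norm):
        best: tuple[int, int] | None = None
        # leftmost start, then shortest total match (shortest loops first)
        for m in _G4_RE.finditer(norm, pos):
            if best is None or m.start() < best[0]:
                end = _shortest_g4_end(norm, m.start())
                best = (m.start(), end)
            break
        if best is None:
            break
        intervals.append(best)
        pos = best[1]
    return bool(intervals), intervals


def _shortest_g4_end(seq: str, start: int) -> int:
    """Smallest end such that seq[start:end] matches the G4 grammar."""
    best = None
    for tract, lo in ((2, 1), (3, 1)):
        for l1 in range(1, 8):
            for l2 in range(1, 8):
                for l3 in range(1, 8):
                    end = start + 4 * tract + l1 + l2 + l3
                    if best is not None and end >= best:
                        continue
                    if end > len(seq):
                        continue
                    p = start
                    ok = True
                    for loop in (l1, l2, l3, None):
                        if seq[p : p + tract] != "G" * tract:
                            ok = False
                            break
                        p += tract + (loop or 0)
                    if ok:
                        best = end
    assert best is not None
    return best


def scan_paired_ggagg(seq: str) -> bool:
    """Paired-GGAGG element: two GGAGG motifs with a 4-10 nt linker."""
    norm = normalize_sequence(seq)
    return _PAIRED_GGAGG_RE.search(norm) is not None


_PATTERN_TOKEN = re.compile(r"[A-Z]|\(|\)|\{\d+(?:,\d*)?\}")


def compile_motif(pattern: str) -> re.Pattern:
    """Compile an IUPAC motif pattern with bounded quantifiers to a regex.

    Grammar: IUPAC nucleotide codes (U allowed, matched as T), round
    brackets for grouping, ``{m}``/``{m,}``/``{m,n}`` repeat counts.
    """
    tokens = _PATTERN_TOKEN.findall(pattern)
    if "".join(tokens) != pattern.replace(" ", ""):
        raise ValueError(f"malformed motif pattern: {pattern!r}")
    out = []
    depth = 0
    prev_atom = False
    for tok in tokens:
        if tok == "(":
            depth += 1
            out.append("(?:")
            prev_atom = False
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced brackets in pattern: {pattern!r}")
            out.append(")")
            prev_atom = True
        elif tok.startswith("{"):
            if not prev_atom:
                raise ValueError(f"quantifier without preceding atom: {pattern!r}")
            out.append(tok)
            prev_atom = False
        else:
            code = "T" if tok == "U" else tok
            if code not in _IUPAC:
                raise ValueError(f"unknown IUPAC code {tok!r} in pattern: {pattern!r}")
            out.append(_IUPAC[code])
            prev_atom = True
    if depth != 0:
        raise ValueError(f"unbalanced brackets in pattern: {pattern!r}")
    return re.compile("".join(out))


def scan_motif(seq: str, pattern: str) -> bool:
    """Presence of an IUPAC motif pattern (see :func:`compile_motif`)."""
    norm = normalize_sequence(seq)
    return compile_motif(pattern).search(norm) is not None


class Folder(Protocol):
    """Pluggable secondary-structure folding engine.

    Must be deterministic, return an MFE <= 0 in kcal/mol, and return
    0.0 for sequences that cannot form any base pair.
    """

    def fold(self, seq: str) -> float: ...


_DNA2RNA = str.maketrans("T", "U")


class ViennaFolder:
    """Thermodynamic minimum free energy via the ViennaRNA package.

    Uses the Python bindings when importable, otherwise shells out to
    ``RNAfold``.  Ambiguous bases (N) are passed through unchanged.
    """

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore

            self._rna = RNA
        except ImportError:  # pragma: no cover - depends on install
            self._rna = None

    def fold(self, seq: str) -> float:
        rna = normalize_sequence(seq).translate(_DNA2RNA)
        if self._rna is not None:
            _, mfe = self._rna.fold(rna)
            return min(float(mfe), 0.0)
        out = subprocess.run(  # pragma: no cover - exercised when bindings absent
            ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True,
            check=True,
        )
        last = out.stdout.strip().splitlines()[-1]
        mfe = float(last.rsplit("(", 1)[1].rstrip(")").strip())
        return min(mfe, 0.0)


class MaxPairingFolder:
    """Non-thermodynamic fallback: maximum canonical base pairing.

    Nussinov-style dynamic program maximizing the number of canonical
    pairs (AT, GC, GT wobble) subject to a minimum hairpin loop of
    ``min_hairpin`` unpaired bases, scored as ``-pair_energy`` kcal/mol
    per pair.  This is a structural capacity score, not a thermodynamic
    free energy; use :class:`ViennaFolder` for real MFE values.
    """

    PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})

    def __init__(self, pair_energy: float = 1.0, min_hairpin: int = 3) -> None:
        if pair_energy <= 0 or min_hairpin < 0:
            raise ValueError("pair_energy must be > 0 and min_hairpin >= 0")
        self.pair_energy = pair_energy
        self.min_hairpin = min_hairpin

    def max_pairs(self, seq: str) -> int:
        s = normalize_sequence(seq)
        n = len(s)
        h = self.min_hairpin
        dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j]: pairs in s[i:j]
        for span in range(h + 2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                best = dp[i + 1, j]  # i unpaired
                for k in range(i + h + 1, j):  # pair i with k
                    if (s[i], s[k]) in self.PAIRS:
                        cand = 1 + dp[i + 1, k] + dp[k + 1, j]
                        if cand > best:
                            best = cand
                dp[i, j] = best
        return int(dp[0, n])

    def fold(self, seq: str) -> float:
        return -self.pair_energy * self.max_pairs(seq)


def fold_energy(seq: str, folder: Folder) -> float:
    """Whole-sequence folding energy from the configured engine.

    Engine failures are flagged as NaN rather than raised.
    """
    try:
        return float(folder.fold(seq))
    except Exception:  # noqa: BLE001 - engine failure becomes missing value
        logger.warning("folding engine failed on a %d-nt sequence", len(seq))
        return float("nan")


def longest_utr_per_gene(records: Iterable[UTRRecord]) -> list[UTRRecord]:
    """One record per gene: the longest UTR, length ties broken by
    lexicographically smallest transcript id."""
    by_gene: dict[str, list[UTRRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    return [
        min(recs, key=lambda r: (-len(r), r.transcript_id))
        for _, recs in sorted(by_gene.items())
    ]


def compute_features(
    records: Iterable[UTRRecord],
    folder: Folder | None = None,
    u_rich_pattern: str = U_RICH_MOTIF,
) -> pd.DataFrame:
    """Full feature table, one row per UTR record.

    Columns: ``gene_id``, ``gc``, ``length``, ``dG`` (NaN when no folder
    is configured), ``n_uaug``, and presence flags ``has_ggc_motif``,
    ``has_gagg_motif``, ``has_urich_motif``, ``has_g4``,
    ``has_paired_ggagg``.
    """
    rows = []
    for rec in records:
        seq = rec.sequence
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "gene_id": rec.gene_id,
                "gc": gc_content(seq),
                "length": len(seq),
                "dG": fold_energy(seq, folder) if folder is not None else float("nan"),
                "n_uaug": count_uaugs(seq),
                "has_ggc_motif": scan_motif(seq, GC_RICH_MOTIF),
                "has_gagg_motif": scan_motif(seq, GA_RICH_MOTIF),
                "has_urich_motif": scan_motif(seq, u_rich_pattern),
                "has_g4": scan_g4(seq),
                "has_paired_ggagg": scan_paired_ggagg(seq),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
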