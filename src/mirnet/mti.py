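"""Compilation of the miRNA-target interaction (MTI) set.

Candidate miRNA-target pairs come from two alignment-based target predictors
(filtered upstream by their penalty scores); pairs predicted by both programs,
or by either program but compatible with degradome (PARE) cleavage evidence,
are combined.  Experimentally validated interactions missed by that pipeline
are then merged in, and candidate sets can be scored against a benchmark of
validated targets.

Pairs are identified at gene level as ``(mirna_id, gene_id)`` tuples.
Typical penalty-score cutoffs are 2.2/2.5 for program A and 2.5/3.0 for
program B (a score at or below the cutoff is kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

Pair = tuple[str, str]

#: provenance labels for compiled MTIs
PROVENANCE = ("both_programs", "both", "degradome_supported", "curated")

#: stringency options for the two predictors (penalty score <= threshold kept)
PROGRAM_A_THRESHOLDS = (2.2, 2.5)
PROGRAM_B_THRESHOLDS = (2.5, 3.0)


def merge_mti(
    pred_a: Iterable[Pair],
    pred_b: Iterable[Pair],
    degradome: Iterable[Pair],
) -> dict[Pair, str]:
    """Combine two predictor outputs with degradome support.

    The result is ``(A ∩ B) ∪ ((A ∪ B) ∩ D)`` where D is the set of
    degradome-supported pairs.  Each retained pair carries a provenance flag:
    ``both_programs`` (both predictors, no degradome), ``both`` (both
    predictors plus degradome) or ``degradome_supported`` (a single predictor
    rescued by degradome evidence).  Empty inputs are allowed.
    """
    a, b, d = set(pred_a), set(pred_b), set(degradome)
    out: dict[Pair, str] = {}
    for pair in a & b:
        out[pair] = "both" if pair in d else "both_programs"
    for pair in (a ^ b) & d:
        out[pair] = "degradome_supported"
    return out


def add_validated(
    pipeline_set: Mapping[Pair, str] | Iterable[Pair],
    curated: Iterable[Pair],
) -> dict[Pair, str]:
    """Union the pipeline MTIs with curated/validated pairs.

    Curated pairs absent from the pipeline are tagged ``curated``; existing
    provenance is preserved, so the final count is
    ``|pipeline| + |curated \\ pipeline|``.
    """
    if isinstance(pipeline_set, Mapping):
        out = dict(pipeline_set)
    else:
        out = {pair: "pipeline" for pair in pipeline_set}
    for pair in curated:
        out.setdefault(pair, "curated")
    return out


def benchmark_eval(
    candidate_sets: Mapping[str, Iterable[Pair]],
    benchmark: Iterable[Pair],
) -> pd.DataFrame:
    """Recovery of a validated benchmark by each candidate MTI set.

    Recovery is |candidate ∩ benchmark| / |benchmark|.  Rows are sorted by
    recovery (descending) then set size (ascending), leaving the choice of
    operating point to the user.
    """
    bench = set(benchmark)
    if not bench:
        raise ValueError("benchmark must be nonempty")
    rows = []
    for name, cand in candidate_sets.items():
        cand = set(cand)
        hit = len(cand & bench)
        rows.append((name, len(cand), hit, hit / len(bench)))
    df = pd.DataFrame(rows, columns=["name", "size", "n_recovered", "recovery"])
    return df.sort_values(["recovery", "size"], ascending=[False, True], ignore_index=True)


# ---------------------------------------------------------------------------
# binding-site position within the transcript
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptStructure:
    """Ordered 5'UTR / CDS / 3'UTR segment lengths of a transcript (nt)."""

    utr5: int
    cds: int
    utr3: int

    def __post_init__(self) -> None:
        if min(self.utr5, self.cds, self.utr3) < 0:
            raise ValueError("segment lengths must be nonnegative")

    @property
    def length(self) -> int:
        return self.utr5 + self.cds + self.utr3

    @property
    def segments(self) -> tuple[tuple[str, int, int], ...]:
        """(label, start, end) half-open transcript intervals, empty ones dropped."""
        out, pos = [], 0
        for label, ln in (("five_prime_utr", self.utr5), ("cds", self.cds),
                          ("three_prime_utr", self.utr3)):
            if ln > 0:
                out.append((label, pos, pos + ln))
            pos += ln
        return tuple(out)


def mbs_relative_position(structure: TranscriptStructure, mbs_start: int) -> tuple[str, float]:
    """Locate a miRNA binding site within the transcript architecture.

    Returns the containing segment label and the position normalised within
    that segment: 0.0 at the segment's first base, 1.0 at its last (a
    single-base segment maps to 0.0).
    """
    if not 0 <= mbs_start < structure.length:
        raise ValueError(f"MBS start {mbs_start} outside transcript of length "
                         f"{structure.length}")
    for label, s, e in structure.segments:
        if s <= mbs_start < e:
            ln = e - s
            return label, (mbs_start - s) / (ln - 1) if ln > 1 else 0.0
    raise AssertionError("unreachable: segments cover the transcript")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_prediction_table(
    path: str | Path,
    program: str | None = None,
    max_score: float | None = None,
) -> set[Pair]:
    """Read a predictor output (``mirna gene [program score]``) into a pair set.

    Rows may optionally be restricted to one program and thresholded by
    penalty score (``score <= max_score``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str}, comment="#")
    if program is not None and "program" in df.columns:
        df = df[df["program"] == program]
    if max_score is not None and "score" in df.columns:
        df = df[df["score"].astype(float) <= max_score]
    return set(zip(df["mirna"], df["gene"]))


def read_degradome_table(path: str | Path) -> set[Pair]:
    """Read degradome support (``mirna gene supported [category]``); returns
    the supported pairs only."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str}, comment="#")
    if "supported" in df.columns:
        mask = df["supported"].astype(str).str.lower().isin(("1", "true", "yes"))
        df = df[mask]
    return set(zip(df["mirna"], df["gene"]))


def read_pair_list(path: str | Path) -> set[Pair]:
    """Two-column TSV (``mirna gene``) used for curated and benchmark lists."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = list(df.columns[:2])
    return set(zip(df[cols[0]], df[cols[1]]))


def mti_edge_table(mtis: Mapping[Pair, str]) -> pd.DataFrame:
    """Render compiled MTIs as an edge table consumable by network assembly."""
    rows = [(m, g, "MTI", "repressing", prov)
            for (m, g), prov in sorted(mtis.items())]
    return pd.DataFrame(rows, columns=["source", "target", "edge_class", "sign", "evidence"])
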