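"""Differential-SV (DSV) detection.

A DSV is a male or offspring SV that cannot be matched, under the wide
tolerance window (1000 bp, type- and strand-aware), to any SV in the
composite maternal callset, and whose region retains adequate maternal
read depth (mean >= 4x by default) — so that absence from the maternal set
reflects a genuine difference rather than a maternal coverage hole.

Maternal subtraction is iterated to a fixpoint: after removing matched
records the match graph is rebuilt and subtraction repeated until an
iteration removes nothing. Cluster-mode subtraction usually converges in
one effective pass, but the loop guards against pairing-heuristic
differences and is the faithful procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .coverage import CoverageTrack
from .match import MergeParams, subtract
from .models import SVCallset, SVType

log = logging.getLogger(__name__)

DSV_MERGE_DEFAULT = MergeParams(1000, 2, True, True, False, 50)


@dataclass(frozen=True)
class DSVParams:
    merge: MergeParams = DSV_MERGE_DEFAULT
    min_maternal_depth: float = 4.0
    max_iterations: int = 10
    coverage_stat: str = "mean"  # "mean" (default) or "min"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class DSVResult:
    sample_id: str
    dsv: SVCallset
    n_input: int
    n_dsv: int
    fraction_of_filtered: float
    iterations_run: int
    n_removed_by_coverage: int
    converged: bool = True


def iterative_maternal_subtraction(
    sample: SVCallset,
    maternal: SVCallset,
    params: DSVParams = DSVParams(),
) -> tuple:
    """Subtract the maternal composite set until a fixpoint is reached.

    Returns ``(remainder, iterations_run, converged)``. ``iterations_run``
    counts every pass including the final no-op one that certifies the
    fixpoint (except when ``max_iterations`` stops the loop first).
    """
    remainder = sample
    iterations = 0
    converged = False
    for _ in range(params.max_iterations):
        iterations += 1
        nxt = subtract(remainder, maternal, params.merge, mode="cluster")
        if len(nxt) == len(remainder):
            converged = True
            remainder = nxt
            break
        remainder = nxt
    if not converged:
        log.warning(
            "%s: maternal subtraction did not certify a fixpoint in %d iterations",
            sample.sample_id,
            params.max_iterations,
        )
        remainder.provenance += "; WARNING: fixpoint not certified"
    return remainder, iterations, converged


def coverage_screen(
    dsvs: SVCallset,
    maternal_coverage: CoverageTrack,
    min_depth: float = 4.0,
    stat: str = "mean",
) -> SVCallset:
    """Drop candidate DSVs over maternally under-covered regions.

    The depth statistic over [pos, end] (the single base at pos for INS)
    must be >= ``min_depth``; below-threshold regions cannot distinguish
    "absent from the mother" from "unobserved in the mother".
    """
    kept = []
    for rec in dsvs:
        end = rec.pos if rec.svtype is SVType.INS else rec.end
        if stat == "mean":
            depth = maternal_coverage.mean_depth(rec.chrom, rec.pos, end)
        elif stat == "min":
            depth = min(
                maternal_coverage.mean_depth(rec.chrom, p, p)
                for p in range(rec.pos, end + 1)
            )
        else:
            raise ValueError(f"unknown coverage stat {stat!r}")
        if depth >= min_depth:
            kept.append(rec)
    return SVCallset(
        dsvs.sample_id,
        kept,
        provenance=f"{dsvs.provenance}; coverage_screen(>= {min_depth})",
    )


def detect_dsv(
    sample: SVCallset,
    maternal: SVCallset,
    maternal_coverage: CoverageTrack,
    params: DSVParams = DSVParams(),
) -> DSVResult:
    """Full DSV detection for one filtered male or offspring callset."""
    n_input = len(sample)
    remainder, iterations, converged = iterative_maternal_subtraction(
        sample, maternal, params
    )
    screened = coverage_screen(
        remainder, maternal_coverage, params.min_maternal_depth, params.coverage_stat
    )
    n_dsv = len(screened)
    return DSVResult(
        sample_id=sample.sample_id,
        dsv=screened,
        n_input=n_input,
        n_dsv=n_dsv,
        fraction_of_filtered=(n_dsv / n_input) if n_input else 0.0,
        iterations_run=iterations,
        n_removed_by_coverage=len(remainder) - n_dsv,
        converged=converged,
    )
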