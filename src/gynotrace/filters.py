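"""Record-level callset filtering.

The standard exclusion rules for male and offspring callsets: drop calls
with QUAL < 20, read support < 4, IMPRECISE breakpoints, missing ("./.")
or homozygous-reference ("0/0") genotypes, any SV class other than
DEL/INS/INV/DUP, and length below 50 bp. All thresholds are strict in the
printed direction: equality is retained (QUAL exactly 20 passes, support
exactly 4 passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet

from .models import Genotype, SVCallset, SVType

DEFAULT_TYPES = frozenset({SVType.DEL, SVType.INS, SVType.INV, SVType.DUP})
DEFAULT_DROP_GT = frozenset({Genotype.MISSING, Genotype.HOM_REF})


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for :func:`filter_callset`.

    ``strict_support`` controls records whose caller reported no read
    support at all: in lenient mode (default) they pass the support rule,
    in strict mode they fail it. The reference pipeline uses strict mode
    for male/offspring callsets, whose caller always reports SUPPORT.
    """

    min_qual: float = 20.0
    min_support: int = 4
    require_precise: bool = True
    drop_genotypes: FrozenSet[Genotype] = DEFAULT_DROP_GT
    allowed_types: FrozenSet[SVType] = DEFAULT_TYPES
    min_abs_len: int = 50
    strict_support: bool = False

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_support < 0 or self.min_abs_len < 0:
            raise ValueError("thresholds must be non-negative")

    def passes(self, rec) -> bool:
        if rec.qual < self.min_qual:
            return False
        if rec.support is None:
            if self.strict_support and self.min_support > 0:
                return False
        elif rec.support < self.min_support:
            return False
        if self.require_precise and not rec.precise:
            return False
        if rec.gt in self.drop_genotypes:
            return False
        if rec.svtype not in self.allowed_types:
            return False
        if rec.abs_len < self.min_abs_len:
            return False
        return True


def filter_callset(callset: SVCallset, params: FilterParams = FilterParams()) -> SVCallset:
    """Return the subset of records passing every threshold, order preserved."""
    kept = [r for r in callset if params.passes(r)]
    prov = (callset.provenance + "; " if callset.provenance else "") + (
        f"filtered(min_qual={params.min_qual}, min_support={params.min_support}, "
        f"precise_only={params.require_precise}, min_len={params.min_abs_len})"
    )
    return SVCallset(callset.sample_id, kept, provenance=prov)
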