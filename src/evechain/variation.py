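"""Per-region SNP/InDel density with breadth masking.

Variants are counted unfiltered, as called; the guard against bias is a
breadth mask — a region/sample combination with less than
``min_breadth_1x`` of its bases covered at >= 1x is excluded from density
(unsequenced bases cannot contribute variants and would drag the density
down), though its variants still appear in cohort totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DepthTable, EveRecord, VariantRecord

__all__ = ["DensityRecord", "snp_density", "density_ratio"]


@dataclass(frozen=True)
class DensityRecord:
    region_id: str
    sample_id: str
    n_variants: int
    length: int
    breadth_1x: float
    masked: bool

    @property
    def density_per_kbp(self) -> float | None:
        if self.masked:
            return None
        return self.n_variants / self.length * 1000.0


def snp_density(variants: Sequence[VariantRecord],
                depths: Mapping[str, DepthTable] | Sequence[DepthTable],
                regions: Sequence[EveRecord],
                min_breadth_1x: float = 0.85) -> list[DensityRecord]:
    """Per (region, sample) variant density in events per kbp.

    A record is masked when the sample covers < ``min_breadth_1x`` of the
    region at >= 1x. SNPs and InDels are counted together; a variant is in
    a region when its position lies within the region's host footprint.
    """
    tables = list(depths.values()) if isinstance(depths, Mapping) else list(depths)
    by_sample: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    out: list[DensityRecord] = []
    for t in tables:
        sample_vars = by_sample.get(t.sample_id, [])
        for region in regions:
            if region.length == 0:
                raise ValueError(f"{region.identifier}: zero-length region")
            count = sum(1 for v in sample_vars
                        if v.chrom == region.chrom and region.h_lo <= v.pos <= region.h_hi)
            breadth = t.breadth(region.chrom, region.h_lo, region.h_hi, min_depth=1)
            out.append(DensityRecord(region_id=region.identifier, sample_id=t.sample_id,
                                     n_variants=count, length=region.length,
                                     breadth_1x=breadth,
                                     masked=breadth < min_breadth_1x))
    return out


def density_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region_id,
                "sample": r.sample_id,
                "n_variants": r.n_variants,
                "length": r.length,
                "breadth_1x": r.breadth_1x,
                "masked": r.masked,
                "density_per_kbp": np.nan if r.masked else r.density_per_kbp,
            }
            for r in records
        ]
    )


def density_ratio(records: Sequence[DensityRecord], baseline_id: str) -> pd.Series:
    """Per-region ratio of pooled variant density to a baseline locus.

    Pools unmasked (region, sample) records: density = total variants /
    total unmasked bases. Masked combinations drop out of both numerator
    and denominator. Raises when the baseline is fully masked or has zero
    density (the ratio is undefined).
    """
    pooled: dict[str, tuple[int, int]] = {}
    for r in records:
        if r.masked:
            continue
        n, length = pooled.get(r.region_id, (0, 0))
        pooled[r.region_id] = (n + r.n_variants, length + r.length)
    if baseline_id not in pooled:
        raise ValueError(f"baseline {baseline_id!r} masked in all samples or absent")
    base_n, base_len = pooled[baseline_id]
    if base_n == 0:
        raise ValueError(f"baseline {baseline_id!r} density is 0: undefined ratio")
    base_density = base_n / base_len
    ratios = {rid: (n / length) / base_density
              for rid, (n, length) in pooled.items()}
    return pd.Series(ratios, name="density_ratio").sort_index()
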