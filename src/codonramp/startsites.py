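"""Alternative AUG start sites: discovery, frame classing, alignment, sampling.

Ribosomes sometimes initiate at AUG triplets upstream (uORFs) or downstream
(leaky scanning) of the annotated start.  This module finds those AUGs,
classes their reading frame relative to the annotated frame (frame 1 = the
annotated frame, frames 2 and 3 = +1 and +2 nt shifts), aligns gene
sequences at the alternative AUGs so periodicity profiles can be computed
in the alternative frame, and draws matched random-AUG comparison sets for
resampling tests.

Offsets are 1-based: an upstream site's offset is the position of its A
within the 5'UTR counted from the UTR's 5' end; a downstream site's offset
is the CDS position of its A (annotated A = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .periodicity import PositionFrequencyMatrix, _pfm_from_counts, _tally
from .seqio import OrfRecord

#: Default scan range for downstream AUGs: CDS nucleotides 2-100 (the
#: annotated start itself, position 1, is excluded).
DEFAULT_DOWNSTREAM_SCAN = (2, 100)


@dataclass(frozen=True)
class AugSite:
    """One alternative AUG: gene, side, 1-based offset, frame, evidence flag."""

    gene_id: str
    location: str  # "upstream" | "downstream"
    offset: int
    frame: int  # 1 = annotated frame, 2/3 = +1/+2 nt shifts
    supported: bool = False


def _frame_from_linear(delta: int) -> int:
    # delta = (0-based index of the site's A) - (0-based index of annotated A)
    return delta % 3 + 1


def find_augs(
    record: OrfRecord,
    location: str,
    scan_range: tuple[int, int] | None = None,
) -> list[AugSite]:
    """All ATG triplets on one side of the annotated start, ordered 5'->3'.

    Downstream scans the CDS over ``scan_range`` (default 2-100, inclusive);
    upstream scans every 5'UTR position (a triplet may run across the
    UTR/CDS junction, since a uORF can overlap the main ORF).  Frames are
    classed relative to the annotated start.  An empty list is valid.
    """
    sites: list[AugSite] = []
    if location == "downstream":
        lo, hi = scan_range if scan_range is not None else DEFAULT_DOWNSTREAM_SCAN
        cds = record.cds
        for o in range(max(lo, 1), min(hi, len(cds) - 2) + 1):
            if cds[o - 1 : o + 2] == "ATG":
                sites.append(
                    AugSite(record.gene_id, "downstream", o, _frame_from_linear(o - 1))
                )
    elif location == "upstream":
        L = len(record.utr5)
        if L == 0:
            return []
        lo, hi = scan_range if scan_range is not None else (1, L)
        span = record.utr5 + record.cds
        for o in range(max(lo, 1), min(hi, L) + 1):
            if span[o - 1 : o + 2] == "ATG":
                sites.append(
                    AugSite(record.gene_id, "upstream", o, _frame_from_linear(o - 1 - L))
                )
    else:
        raise ValueError(f"location must be 'upstream' or 'downstream', got {location!r}")
    return sites


def align_at_augs(
    records: Iterable[OrfRecord],
    sites: Sequence[AugSite],
    positions: Sequence[int],
) -> PositionFrequencyMatrix:
    """Pool positional counts over sequences anchored at each site's AUG.

    The A of each AUG is position 1, so downstream windows (e.g. 7-22) feed
    ``codon_window_stat`` in the alternative AUG's own reading frame.
    Sequence is taken from the full utr5+cds+utr3 span; positions falling
    off a gene simply do not contribute.
    """
    positions = tuple(int(p) for p in positions)
    if not positions:
        raise ValueError("empty position range")
    by_id = {r.gene_id: r for r in records}
    items = []
    for site in sites:
        try:
            rec = by_id[site.gene_id]
        except KeyError:
            raise ValueError(f"unresolvable gene_id in site list: {site.gene_id!r}") from None
        span = rec.spanning
        if site.location == "upstream":
            a0 = site.offset - 1
        else:
            a0 = len(rec.utr5) + site.offset - 1
        items.append((span, a0, 0, len(span)))
    counts, _ = _tally(items, positions)
    return _pfm_from_counts("alt_aug", positions, counts, len(items))


def sample_random_augs(
    sites: Sequence[AugSite], n: int, seed: int = 0
) -> list[AugSite]:
    """Uniform without-replacement sample of n sites, reproducible by seed.

    Frame/location matching is by construction: sampling stays within the
    provided list, so callers pass the pre-filtered comparison set (e.g.
    all frame-2 downstream AUGs).
    """
    if n > len(sites):
        raise ValueError(f"cannot sample {n} from {len(sites)} sites")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sites), size=n, replace=False)
    return [sites[i] for i in idx]


def write_aug_sites(sites: Iterable[AugSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "location": s.location,
                "offset": s.offset,
                "frame": s.frame,
                "supported": str(s.supported),
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_aug_sites(path: str | Path) -> list[AugSite]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        AugSite(
            gene_id=row.gene_id,
            location=row.location,
            offset=int(row.offset),
            frame=int(row.frame),
            supported=str(row.supported).strip().lower() in {"1", "true", "t", "yes"},
        )
        for row in df.itertuples(index=False)
    ]
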