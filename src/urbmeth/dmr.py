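"""Differentially methylated regions: >=3 DMSs within a 2 kb window.

DMSs are clustered left to right: the caller repeatedly takes the earliest
maximal run of consecutive sites whose span (first to last member, inclusive)
fits in the window and which has at least ``min_sites`` members, emits it as
a DMR, and continues after it. Each DMS belongs to at most one DMR. A DMR is
classed constitutive_hyper / constitutive_hypo when every member shifts the
same way in urban birds, otherwise mixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DIRECTION_CLASSES = ("constitutive_hyper", "constitutive_hypo", "mixed")


def classify_directions(directions) -> str:
    directions = list(directions)
    if not directions:
        raise ValueError("cannot classify an empty DMR")
    if all(d == "hyper" for d in directions):
        return "constitutive_hyper"
    if all(d == "hypo" for d in directions):
        return "constitutive_hypo"
    return "mixed"


def call_dmrs(dms: pd.DataFrame, window: int = 2000, min_sites: int = 3) -> pd.DataFrame:
    """Cluster a DMS table (chrom, pos, direction) into DMRs.

    Returns one row per DMR: chrom, start, end (member span, half-open),
    n_sites, member_pos (tuple), direction_class. Output is invariant to the
    input row order; every reported region satisfies end - start <= window
    and n_sites >= min_sites.
    """
    cols = ["chrom", "start", "end", "n_sites", "member_pos", "direction_class"]
    if dms.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, grp in dms.sort_values(["chrom", "pos"]).groupby("chrom", sort=True):
        pos = grp.pos.to_numpy()
        dirs = grp.direction.to_numpy() if "direction" in grp else np.array(["hyper"] * len(grp))
        n = len(pos)
        i = 0
        while i < n:
            # maximal run starting at i with span <= window
            j = int(np.searchsorted(pos, pos[i] + window, side="left"))  # pos[j-1] - pos[i] + 1 <= window
            if j - i >= min_sites:
                members = pos[i:j]
                rows.append((chrom, int(members[0]), int(members[-1]) + 1, j - i,
                             tuple(int(x) for x in members),
                             classify_directions(dirs[i:j])))
                i = j
            else:
                i += 1
    out = pd.DataFrame(rows, columns=cols)
    assert ((out.end - out.start) <= window).all()
    assert (out.n_sites >= min_sites).all()
    return out


def dms_in_dmr_mask(dms: pd.DataFrame, dmrs: pd.DataFrame) -> np.ndarray:
    """Boolean mask over the DMS table rows: member of any DMR."""
    members = {(row.chrom, p) for row in dmrs.itertuples(index=False)
               for p in row.member_pos}
    return np.array([(c, p) in members for c, p in zip(dms.chrom, dms.pos)])
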