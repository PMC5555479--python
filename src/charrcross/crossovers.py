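"""Crossover detection and genotyping-error-aware double-crossover correction.

Detection reads each offspring's ordered haplotype labels for one parent
along one linkage group and emits one event per change of label between
consecutive informative markers — the minimum number of obligate phase
switches consistent with the observations (unknown labels are skipped;
a change across a run of unknowns is a single event at the midpoint of
the bounding known markers).

A single genotyping error in the middle of a chromosome masquerades as a
pair of tight double crossovers.  The correction chains nearby events
into clusters (by default while the gap to the previous event is at most
W = 50 cM) and removes clusters with an even member count — they produce
no net phase change, the signature of an error rather than of real
recombination.  Odd clusters larger than one are collapsed to a single
representative at the median member, preserving the net phase change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (BOTH_INFORMATIVE, EVENT_COLUMNS, GeneticMap,
                 PhasedGenotypes, UNKNOWN)

PARENTS = ("dam", "sire")

RETAINED = "retained"
REMOVED = "removed"
COLLAPSED = "collapsed_representative"


@dataclass
class CorrectionParams:
    """Windowed even-parity correction settings.

    window: search radius W in cM (study default 50; 25 and 10 are the
    standard sensitivity variants).  chaining 'gap' joins an event to the
    current cluster while its gap to the previous event is <= W; 'anchor'
    joins while it is within W of the cluster's first event.
    odd_cluster 'collapse_to_one' keeps the median member of odd clusters
    (>1); 'keep_all' keeps every member of odd clusters.
    """

    window: float = 50.0
    chaining: str = "gap"  # gap | anchor
    odd_cluster: str = "collapse_to_one"  # collapse_to_one | keep_all

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.chaining not in ("gap", "anchor"):
            raise ValueError(f"unknown chaining mode {self.chaining!r}")
        if self.odd_cluster not in ("collapse_to_one", "keep_all"):
            raise ValueError(f"unknown odd_cluster policy {self.odd_cluster!r}")


def _representative(mids: np.ndarray) -> int:
    """Index of the retained member of an odd cluster (size >= 3).

    A genotyping error leaves a tight pair of spurious events; when a
    real crossover chains into such a cluster, the sorted median is
    always a member of the tight pair, so the median rule would keep a
    spurious event and misplace the surviving crossover.  Instead keep
    the member most isolated from its within-cluster neighbours
    (max-min gap); exact ties fall back to the median member, so evenly
    spaced clusters collapse to their middle event.
    """
    k = len(mids)
    gaps = np.diff(mids)
    iso = np.empty(k)
    iso[0] = gaps[0]
    iso[-1] = gaps[-1]
    if k > 2:
        iso[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    best = np.flatnonzero(iso == iso.max())
    mid = k // 2
    return int(best[np.argmin(np.abs(best - mid))])


def min_switch_count(labels) -> int:
    """Minimum number of phase switches consistent with a label sequence.

    ``labels`` holds 0/1 for the two parental haplotypes and -1 for
    unknown.  Unknowns never force a switch; the minimum equals the number
    of changes between consecutive known labels.
    """
    last = -1
    n = 0
    for x in labels:
        if x < 0:
            continue
        if last >= 0 and x != last:
            n += 1
        last = x
    return n


def parental_phase_sequence(genotypes: PhasedGenotypes, gmap: GeneticMap,
                            offspring: str, lg: str, parent: str,
                            informative_both_only: bool = False):
    """Ordered (positions, labels) for one offspring/parent on one LG.

    Labels are 0/1/-1 (see ``min_switch_count``).  With
    ``informative_both_only`` the marker set is restricted to types
    informative in both parents (efxeg, hkxhk), as heterochiasmy
    comparisons require to avoid a one-sex marker-density bias.
    """
    sub = gmap.lg_markers(lg)
    sub = sub[sub.index.isin(genotypes.codes.columns)]
    if informative_both_only:
        sub = sub[sub["seg_type"].isin(BOTH_INFORMATIVE)]
    cols = sub.index
    mat = genotypes.dam if parent == "dam" else genotypes.sire
    labels = mat.loc[offspring, cols].to_numpy(dtype=np.int8)
    return sub["pos_cM"].to_numpy(float), labels


def _row_events(pos: np.ndarray, labels: np.ndarray, marker_ids):
    """Yield (left_idx, right_idx, midpoint) per obligate switch."""
    known = np.flatnonzero(labels >= 0)
    if known.size < 2:
        return []
    lab = labels[known]
    change = np.flatnonzero(lab[1:] != lab[:-1])
    out = []
    for c in change:
        i, j = known[c], known[c + 1]
        out.append((i, j, 0.5 * (pos[i] + pos[j])))
    return out


def detect_crossovers(genotypes: PhasedGenotypes, gmap: GeneticMap,
                      informative_both_only: bool = False,
                      parents=PARENTS) -> pd.DataFrame:
    """Raw crossover events for every offspring × parent × LG.

    Returns the standard event table (one row per event, status
    'retained', cluster unset); midpoints are means of the flanking
    informative-marker positions and percent_pos is the midpoint as a
    percentage of the LG length (last marker position on the full map).
    """
    rows = []
    for lg in gmap.lgs:
        full = gmap.lg_markers(lg)
        length = float(full["pos_cM"].max())
        sub = full[full.index.isin(genotypes.codes.columns)]
        if informative_both_only:
            sub = sub[sub["seg_type"].isin(BOTH_INFORMATIVE)]
        if len(sub) == 0:
            continue
        pos = sub["pos_cM"].to_numpy(float)
        ids = np.asarray(sub.index)
        for parent in parents:
            mat = genotypes.dam if parent == "dam" else genotypes.sire
            block = mat[list(sub.index)].to_numpy(dtype=np.int8)
            for r, off in enumerate(genotypes.codes.index):
                for i, j, mid in _row_events(pos, block[r], ids):
                    rows.append((off, parent, lg, ids[i], pos[i], ids[j],
                                 pos[j], mid,
                                 100.0 * mid / length if length > 0 else np.nan,
                                 -1, RETAINED))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def count_obligate(genotypes: PhasedGenotypes, gmap: GeneticMap,
                   informative_both_only: bool = False) -> pd.Series:
    """Raw obligate crossover count per offspring (both parents, all LGs)."""
    counts = pd.Series(0, index=genotypes.codes.index, dtype=int)
    for lg in gmap.lgs:
        sub = gmap.lg_markers(lg)
        sub = sub[sub.index.isin(genotypes.codes.columns)]
        if informative_both_only:
            sub = sub[sub["seg_type"].isin(BOTH_INFORMATIVE)]
        if len(sub) == 0:
            continue
        for parent in PARENTS:
            mat = genotypes.dam if parent == "dam" else genotypes.sire
            block = mat[list(sub.index)].to_numpy(dtype=np.int8)
            for r in range(block.shape[0]):
                counts.iloc[r] += min_switch_count(block[r])
    return counts


def _cluster_ids(midpoints: np.ndarray, params: CorrectionParams) -> np.ndarray:
    """Cluster labels (0..k-1) for sorted midpoints on one haplotype."""
    n = len(midpoints)
    ids = np.zeros(n, dtype=int)
    if n == 0:
        return ids
    if params.chaining == "gap":
        breaks = np.diff(midpoints) > params.window
        ids[1:] = np.cumsum(breaks)
    else:  # anchor
        cid, anchor = 0, midpoints[0]
        for k in range(1, n):
            if midpoints[k] - anchor > params.window:
                cid += 1
                anchor = midpoints[k]
            ids[k] = cid
    return ids


def correct_double_crossovers(events: pd.DataFrame,
                              params: CorrectionParams) -> pd.DataFrame:
    """Assign cluster ids and statuses to one haplotype's sorted events.

    ``events`` must all belong to one (offspring, parent, lg).  Even
    clusters are removed entirely (no net phase change — putative
    genotyping error); odd clusters > 1 are collapsed to one retained
    representative (see :func:`_representative`) or fully kept under
    'keep_all'; singletons are retained.
    """
    ev = events.sort_values("midpoint", kind="stable").copy()
    mids = ev["midpoint"].to_numpy(float)
    cids = _cluster_ids(mids, params)
    status = np.full(len(ev), RETAINED, dtype=object)
    for cid in np.unique(cids):
        members = np.flatnonzero(cids == cid)
        k = members.size
        if k == 1:
            continue
        if k % 2 == 0:
            status[members] = REMOVED
        elif params.odd_cluster == "collapse_to_one":
            status[members] = REMOVED
            status[members[_representative(mids[members])]] = COLLAPSED
        # keep_all: leave retained
    ev["cluster"] = cids
    ev["status"] = status
    return ev


def apply_correction(events: pd.DataFrame,
                     params: CorrectionParams | None = None) -> pd.DataFrame:
    """Run the correction independently per (offspring, parent, lg).

    Vectorized equivalent of calling :func:`correct_double_crossovers`
    on every haplotype's event list; insertion order of ``events`` does
    not affect the result.
    """
    params = params or CorrectionParams()
    if len(events) == 0:
        return events.copy()
    ev = events.sort_values(["offspring", "parent", "lg", "midpoint"],
                            kind="stable", ignore_index=True)
    n = len(ev)
    key = (ev["offspring"].astype(str) + "\x00" + ev["parent"].astype(str)
           + "\x00" + ev["lg"].astype(str))
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = key.to_numpy()[1:] != key.to_numpy()[:-1]
    mids = ev["midpoint"].to_numpy(float)

    if params.chaining == "gap":
        new_cluster = new_group.copy()
        new_cluster[1:] |= (mids[1:] - mids[:-1]) > params.window
    else:  # anchor: running reference to the cluster's first event
        new_cluster = np.empty(n, dtype=bool)
        anchor = mids[0]
        for i in range(n):
            if new_group[i] or mids[i] - anchor > params.window:
                new_cluster[i] = True
                anchor = mids[i]
            else:
                new_cluster[i] = False

    cid = np.cumsum(new_cluster) - 1
    sizes = np.bincount(cid)
    starts = np.flatnonzero(new_cluster)
    csize = sizes[cid]
    status = np.full(n, RETAINED, dtype=object)
    status[(csize >= 2) & (csize % 2 == 0)] = REMOVED
    if params.odd_cluster == "collapse_to_one":
        status[(csize >= 3) & (csize % 2 == 1)] = REMOVED
        for c in np.flatnonzero((sizes >= 3) & (sizes % 2 == 1)):
            members = np.arange(starts[c], starts[c] + sizes[c])
            status[members[_representative(mids[members])]] = COLLAPSED

    # cluster ids restart at 0 within each haplotype
    gid = np.cumsum(new_group) - 1
    cid_at_group_start = cid[np.flatnonzero(new_group)]
    ev["cluster"] = cid - cid_at_group_start[gid]
    ev["status"] = status
    return ev.sort_values(["lg", "parent", "offspring", "midpoint"],
                          kind="stable", ignore_index=True)


def retained(events: pd.DataFrame) -> pd.DataFrame:
    """Events that survive the correction (retained + collapsed reps)."""
    return events[events["status"] != REMOVED]


def removed_totals(events: pd.DataFrame, gmap: GeneticMap) -> dict:
    """Removed-event totals per parent, autosomes and sex LG separately."""
    sex_lg = gmap.sex_lg
    rem = events[events["status"] == REMOVED]
    on_sex = rem["lg"] == sex_lg
    out = {}
    for parent in PARENTS:
        p = rem["parent"] == parent
        out[parent] = {
            "autosomes": int((p & ~on_sex).sum()),
            "sex_lg": int((p & on_sex).sum()),
        }
    return out
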