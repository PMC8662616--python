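"""Gillespie simulation of indel evolution along a rooted tree.

The root sequence has RL placeholder residues. Along each branch the
process waits exponential times with total intensity

    lambda(L) = R_ins * (L + 1) + R_del * L

per unit branch length (branch lengths are substitutions/site and the
rates are ratios to the substitution rate). Insertions have one slot per
inter-residue position plus both ends, hence L + 1; deletions act per
residue, hence L. When an event fires its type is chosen proportionally
to the two intensity terms and its length is then drawn from the
truncated Zipf law of that type.

An insertion of length l is placed uniformly over the L + 1 slots
(slot k = "insert before residue k", 0-based, k = L appends). A deletion
of length l starts uniformly over {-(l-1), ..., L-1} and only its
overlap with [0, L-1] is removed — the widened window is the boundary
correction that keeps the per-residue deletion rate uniform up to and
including the termini (a start of -1 with l = 5 deletes the first four
residues). Events whose cumulative waiting time exceeds the branch
length are discarded. A sequence of length 0 keeps insertion intensity
R_ins (one slot), so lineages can revive; deletions are then impossible.

Homology is tracked with unique integer site ids: the true alignment is
read off the global site ordering, and the returned MSA never contains
all-gap columns (sites surviving in no leaf are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np

from .msa import Msa
from .params import IndelParams
from .trees import PhyloTree
from .zipf import zipf_cdf

INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class IndelEvent:
    """One indel event on one branch.

    ``position`` follows the placement conventions above: an insertion
    slot in [0, L] or a deletion start in [-(length-1), L-1], both
    relative to the sequence state at the moment the event fired.
    """

    branch: int
    time: float
    kind: str
    length: int
    position: int


@dataclass
class EventHistory:
    """Every indel event of one simulation, by pre-order branch index.

    Replaying the history deterministically reconstructs the length of
    every node's sequence (see :func:`replay_leaf_lengths`).
    """

    root_length: int
    events: dict[int, list[IndelEvent]] = field(default_factory=dict)

    def all_events(self) -> list[IndelEvent]:
        out: list[IndelEvent] = []
        for branch in sorted(self.events):
            out.extend(self.events[branch])
        return out


def _gillespie_branch(
    length: int,
    ins_rate: float,
    del_rate: float,
    ins_cdf: np.ndarray,
    del_cdf: np.ndarray,
    t_branch: float,
    rng: np.random.Generator,
    branch: int,
) -> list[IndelEvent]:
    """Event times/types/lengths/positions for one branch, state replayed
    on ``length`` only (positions are valid against the evolving state)."""
    events: list[IndelEvent] = []
    t = 0.0
    L = length
    while True:
        lam_ins = ins_rate * (L + 1)
        lam_del = del_rate * L
        total = lam_ins + lam_del
        if total <= 0.0:
            break
        t += -log(1.0 - rng.random()) / total
        if t > t_branch:
            break
        if rng.random() * total < lam_ins:
            ell = int(np.searchsorted(ins_cdf, rng.random(), side="right")) + 1
            k = int(rng.integers(0, L + 1))
            events.append(IndelEvent(branch, t, INSERTION, ell, k))
            L += ell
        else:
            ell = int(np.searchsorted(del_cdf, rng.random(), side="right")) + 1
            start = int(rng.integers(-(ell - 1), L))
            events.append(IndelEvent(branch, t, DELETION, ell, start))
            lo = max(start, 0)
            hi = min(start + ell, L)
            L -= hi - lo
    return events


def apply_event_to_length(L: int, ev: IndelEvent) -> int:
    """Sequence length after one event (boundary-corrected deletions)."""
    if ev.kind == INSERTION:
        return L + ev.length
    lo = max(ev.position, 0)
    hi = min(ev.position + ev.length, L)
    return L - max(hi - lo, 0)


def evolve_branch(
    seq_len: int,
    params: IndelParams,
    t: float,
    rng: np.random.Generator,
    *,
    max_indel_len: int = 50,
    branch: int = 0,
) -> tuple[int, list[IndelEvent]]:
    """Evolve a sequence of ``seq_len`` residues for branch length ``t``.

    Returns the final length and the ordered event list. ``t`` may be 0,
    in which case no events occur.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    ins_cdf = zipf_cdf(params.insertion_a, max_indel_len)
    del_cdf = zipf_cdf(params.deletion_a, max_indel_len)
    events = _gillespie_branch(
        seq_len,
        params.insertion_rate,
        params.deletion_rate,
        ins_cdf,
        del_cdf,
        t,
        rng,
        branch,
    )
    L = seq_len
    for ev in events:
        L = apply_event_to_length(L, ev)
    return L, events


def _simulate_ids(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    max_indel_len: int,
    record_events: bool,
):
    """Core traversal: pre-order over branches, site-id bookkeeping.

    Returns (archive order of all site ids, per-leaf id lists, history).
    """
    flat = tree.flat
    ins_rate = params.insertion_rate
    del_rate = params.deletion_rate
    ins_cdf = zipf_cdf(params.insertion_a, max_indel_len)
    del_cdf = zipf_cdf(params.deletion_a, max_indel_len)
    rl = params.root_length

    archive = list(range(rl))
    next_id = rl
    n_nodes = len(flat.parent)
    seqs: list[Optional[list[int]]] = [None] * n_nodes
    seqs[0] = list(range(rl))
    history = EventHistory(root_length=rl) if record_events else None

    rng_random = rng.random
    rng_integers = rng.integers
    for node in range(1, n_nodes):
        seq = list(seqs[flat.parent[node]])
        t_branch = flat.blen[node]
        t = 0.0
        ev_list: list[IndelEvent] = []
        while True:
            L = len(seq)
            lam_ins = ins_rate * (L + 1)
            lam_del = del_rate * L
            total = lam_ins + lam_del
            if total <= 0.0:
                break
            t += -log(1.0 - rng_random()) / total
            if t > t_branch:
                break
            if rng_random() * total < lam_ins:
                ell = int(np.searchsorted(ins_cdf, rng_random(), side="right")) + 1
                k = int(rng_integers(0, L + 1))
                new_ids = list(range(next_id, next_id + ell))
                next_id += ell
                # keep the global column order consistent with this lineage
                if L == 0:
                    pos = len(archive)
                elif k < L:
                    pos = archive.index(seq[k])
                else:
                    pos = archive.index(seq[L - 1]) + 1
                archive[pos:pos] = new_ids
                seq[k:k] = new_ids
                if record_events:
                    ev_list.append(IndelEvent(node, t, INSERTION, ell, k))
            else:
                ell = int(np.searchsorted(del_cdf, rng_random(), side="right")) + 1
                start = int(rng_integers(-(ell - 1), L))
                lo = max(start, 0)
                hi = min(start + ell, L)
                if hi > lo:
                    del seq[lo:hi]
                if record_events:
                    ev_list.append(IndelEvent(node, t, DELETION, ell, start))
        seqs[node] = seq
        if record_events and ev_list:
            history.events[node] = ev_list

    leaf_seqs = [seqs[i] for i in flat.leaf_nodes]
    return archive, leaf_seqs, history


def simulate_gap_matrix(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    *,
    max_indel_len: int = 50,
) -> np.ndarray:
    """Boolean gap matrix of the true alignment (no event record).

    Fast path used inside the ABC loop; identical process to
    :func:`simulate_alignment`.
    """
    archive, leaf_seqs, _ = _simulate_ids(tree, params, rng, max_indel_len, False)
    return _gap_matrix_from_ids(archive, leaf_seqs)


def _gap_matrix_from_ids(archive, leaf_seqs) -> np.ndarray:
    present: set[int] = set()
    for seq in leaf_seqs:
        present.update(seq)
    cols = [sid for sid in archive if sid in present]
    col_index = {sid: i for i, sid in enumerate(cols)}
    n = len(leaf_seqs)
    gap = np.ones((n, len(cols)), dtype=bool)
    for row, seq in enumerate(leaf_seqs):
        if seq:
            gap[row, [col_index[sid] for sid in seq]] = False
    return gap


def simulate_alignment(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    *,
    max_indel_len: int = 50,
    residue: str = "A",
) -> tuple[Msa, EventHistory]:
    """Simulate indel evolution and return the true alignment.

    Substitutions are not simulated (the gap pattern is independent of
    residue identity); every residue is the placeholder ``residue``.
    Use :func:`indelabc.substitutions.overlay_substitutions` to add
    residue evolution when realistic sequences are needed.
    """
    archive, leaf_seqs, history = _simulate_ids(tree, params, rng, max_indel_len, True)
    gap = _gap_matrix_from_ids(archive, leaf_seqs)
    rows = []
    for r in range(gap.shape[0]):
        chars = np.where(gap[r], "-", residue)
        rows.append("".join(chars))
    labels = list(tree.leaf_labels)
    if gap.shape[1] == 0:
        # every site deleted in every surviving lineage: represent as a
        # single all-gap-free empty alignment is impossible; keep 0 cols
        msa = Msa.__new__(Msa)
        msa.labels = labels
        msa.sequences = [""] * len(labels)
        msa._gap_matrix = gap
        return msa, history
    return Msa(labels, rows), history


def replay_leaf_lengths(tree: PhyloTree, history: EventHistory) -> dict[str, int]:
    """Reconstruct every leaf's ungapped length from the event record.

    Independent of the alignment assembly: only lengths are replayed,
    branch by branch in pre-order.
    """
    flat = tree.flat
    n_nodes = len(flat.parent)
    lengths = [0] * n_nodes
    lengths[0] = history.root_length
    for node in range(1, n_nodes):
        L = lengths[flat.parent[node]]
        for ev in history.events.get(node, ()):
            L = apply_event_to_length(L, ev)
        lengths[node] = L
    return {
        lab: lengths[idx]
        for lab, idx in zip(flat.leaf_labels, flat.leaf_nodes)
    }
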