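"""Pair-table curation, cluster-coherent fold planning, and fixtures.

Curation operates on generic TSV pair tables (columns ``id_a``, ``id_b``,
``label``, optional ``evidence_count``): conflicts between the positive and
negative tables are resolved in favour of the positive evidence, duplicate
unordered pairs are collapsed, self-interactions dropped, and redundant
pairs (matching chains with high sequence identity and the same label)
pruned, keeping the pair whose proteins have more recorded interactions.

Fold planning assigns whole sequence-similarity clusters to folds so that
similar proteins never straddle the train/test boundary, and keeps all five
predicted models of a pair in the same fold.  Training uses every available
model of a pair; testing uses model 1 only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import numpy as np

from .synthetic import (FixtureSpec, FixtureError,  # noqa: F401
                        build_fixture_complex, generate_fixture_complex)

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.40
N_MODELS = 5


class DatasetError(ValueError):
    pass


def pair_key(id_a: str, id_b: str) -> tuple[str, str]:
    """Canonical unordered pair key (sorted ids)."""
    return tuple(sorted((str(id_a), str(id_b))))


@dataclass
class PairRecord:
    id_a: str
    id_b: str
    label: int  # 1 positive, 0 negative
    evidence_count: int = 1
    model_paths: dict = field(default_factory=dict)  # model index -> path

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.id_a, self.id_b)


@dataclass
class FoldPlan:
    k: int
    assignment: dict  # pair key -> fold index
    cluster_map: dict  # protein id -> cluster id

    def pairs_in_fold(self, fold: int) -> list[tuple[str, str]]:
        return sorted(k for k, f in self.assignment.items() if f == fold)

    def validate(self) -> None:
        """Independent post-hoc check of the fold constraints."""
        folds_of_cluster: dict = {}
        for (a, b), f in self.assignment.items():
            for pid in (a, b):
                cl = self.cluster_map[pid]
                folds_of_cluster.setdefault(cl, set()).add(f)
        split = {cl for cl, fs in folds_of_cluster.items() if len(fs) > 1}
        if split:
            raise DatasetError(f"clusters split across folds: {sorted(split)}")
        if set(self.assignment.values()) - set(range(self.k)):
            raise DatasetError("fold index out of range")

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "assignment": {f"{a}\t{b}": f for (a, b), f
                           in sorted(self.assignment.items())},
            "cluster_map": dict(sorted(self.cluster_map.items())),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        assignment = {tuple(k.split("\t")): v
                      for k, v in d["assignment"].items()}
        return cls(k=d["k"], assignment=assignment,
                   cluster_map=d["cluster_map"])


def read_pair_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"id_a": str, "id_b": str})
    if "evidence_count" not in df.columns:
        df["evidence_count"] = 1
    return df


def read_cluster_map(path_or_buf) -> dict:
    """Read an id -> cluster TSV (easy-cluster dialect: representative,
    member)."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None,
                     names=["rep", "member"], dtype=str)
    return {row.member: row.rep for row in df.itertuples()}


def greedy_cluster(ids, similarity, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> dict:
    """Single-linkage greedy clustering fallback on an identity function.

    ``similarity(p, q)`` returns pairwise identity in [0, 1].  Used when no
    external cluster table (e.g. an easy-cluster run) is supplied.
    """
    ids = sorted(set(ids))
    cluster: dict = {}
    for pid in ids:
        assigned = None
        for qid in cluster:
            if similarity(pid, qid) >= threshold:
                assigned = cluster[qid]
                break
        cluster[pid] = assigned if assigned is not None else pid
    # single linkage: compress transitively
    changed = True
    while changed:
        changed = False
        for pid, cl in list(cluster.items()):
            if cluster.get(cl, cl) != cl:
                cluster[pid] = cluster[cl]
                changed = True
    return cluster


def curate_pairs(positives: pd.DataFrame, negatives: pd.DataFrame,
                 similarity=None,
                 identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                 ) -> list[PairRecord]:
    """Apply the curation rules to positive/negative pair tables.

    1. pairs present in both tables are removed from the negative side;
    2. duplicate unordered pairs are collapsed (evidence counts summed);
    3. self-pairs are dropped;
    4. among same-label pairs with matching, highly similar chains, only
       the pair whose proteins have the most recorded interactions is kept;
    5. proteins lacking at least one positive and one negative pair are
       reported with a warning.
    """
    def collapse(df: pd.DataFrame, label: int) -> dict:
        out: dict = {}
        for row in df.itertuples():
            if str(row.id_a) == str(row.id_b):
                continue  # self-interaction
            k = pair_key(row.id_a, row.id_b)
            ev = int(getattr(row, "evidence_count", 1))
            if k in out:
                out[k].evidence_count += ev
            else:
                out[k] = PairRecord(k[0], k[1], label, ev)
        return out

    pos = collapse(positives, 1)
    neg = collapse(negatives, 0)
    conflicts = set(pos) & set(neg)
    if conflicts:
        logger.info("removing %d conflicting pairs from the negative set",
                    len(conflicts))
    for k in conflicts:
        del neg[k]

    records = list(pos.values()) + list(neg.values())

    if similarity is not None:
        records = _prune_redundant(records, similarity, identity_threshold)

    if not records:
        raise DatasetError("curation produced an empty pair set")

    _warn_unbalanced(records)
    return sorted(records, key=lambda r: (1 - r.label, r.key))


def _degree(records) -> dict:
    deg: dict = {}
    for r in records:
        for pid in r.key:
            deg[pid] = deg.get(pid, 0) + 1
    return deg


def _prune_redundant(records, similarity, threshold):
    degree = _degree(records)

    def matched(r1: PairRecord, r2: PairRecord) -> bool:
        a1, b1 = r1.key
        a2, b2 = r2.key
        straight = (similarity(a1, a2) >= threshold
                    and similarity(b1, b2) >= threshold)
        crossed = (similarity(a1, b2) >= threshold
                   and similarity(b1, a2) >= threshold)
        return straight or crossed

    records = sorted(records, key=lambda r: (1 - r.label, r.key))
    dropped: set = set()
    for i, r1 in enumerate(records):
        if r1.key in dropped:
            continue
        for r2 in records[i + 1:]:
            if r2.key in dropped or r2.label != r1.label:
                continue
            if matched(r1, r2):
                # keep the pair whose interactors have more interactions
                d1 = degree[r1.key[0]] + degree[r1.key[1]]
                d2 = degree[r2.key[0]] + degree[r2.key[1]]
                loser = r2 if d2 < d1 else (r1 if d1 < d2 else r2)
                dropped.add(loser.key)
                logger.info("redundancy: dropping pair %s", loser.key)
                if loser is r1:
                    break
    return [r for r in records if r.key not in dropped]


def _warn_unbalanced(records) -> list:
    has_pos: set = set()
    has_neg: set = set()
    for r in records:
        target = has_pos if r.label == 1 else has_neg
        target.update(r.key)
    unbalanced = sorted((has_pos | has_neg) - (has_pos & has_neg))
    if unbalanced:
        logger.warning(
            "%d proteins lack the >=1 positive and >=1 negative balance: %s",
            len(unbalanced), unbalanced[:10])
    return unbalanced


def make_folds(pairs, cluster_map, k: int = 5, seed: int = 0) -> FoldPlan:
    """Assign pairs to k folds, keeping every cluster within one fold.

    Pairs whose protein clusters are linked (directly or transitively
    through shared pairs) form indivisible groups; groups are dealt to the
    currently smallest fold, largest group first, with a seeded random
    tie-break.  A group holding more than 40% of the pairs cannot be
    balanced and is an error (re-cluster at a higher identity threshold).
    """
    for r in pairs:
        for pid in r.key:
            if pid not in cluster_map:
                raise DatasetError(f"protein {pid!r} missing from cluster map")

    # union-find over cluster ids, linked by pairs
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for r in pairs:
        union(cluster_map[r.key[0]], cluster_map[r.key[1]])

    groups: dict = {}
    for r in pairs:
        root = find(cluster_map[r.key[0]])
        groups.setdefault(root, []).append(r)

    biggest = max(len(g) for g in groups.values())
    if biggest > 0.4 * len(pairs):
        raise DatasetError(
            "a single cluster group holds more than 40% of the pairs; "
            "re-cluster at a stricter identity threshold")

    rng = np.random.default_rng(seed)
    order = sorted(groups, key=lambda g: (-len(groups[g]), str(g)))
    # seeded shuffle among equal-sized groups
    sizes = np.array([len(groups[g]) for g in order])
    shuffled = []
    for size in sorted(set(sizes), reverse=True):
        block = [g for g in order if len(groups[g]) == size]
        rng.shuffle(block)
        shuffled.extend(block)

    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict = {}
    for g in shuffled:
        f = int(np.argmin(fold_sizes))
        for r in groups[g]:
            assignment[r.key] = f
        fold_sizes[f] += len(groups[g])

    plan = FoldPlan(k=k, assignment=assignment, cluster_map=dict(cluster_map))
    plan.validate()
    return plan


def expand_training_items(plan: FoldPlan, fold: int, pairs):
    """Split pairs into train items (all models of out-of-fold pairs) and
    test items (model 1 only of in-fold pairs).

    Items are ``(pair_key, model_index, path)`` triples; ``path`` is None
    when the record carries no file manifest (synthetic pipelines render
    on the fly).
    """
    if not 0 <= fold < plan.k:
        raise DatasetError(f"fold {fold} outside 0..{plan.k - 1}")
    by_key = {r.key: r for r in pairs}
    train, test = [], []
    for key, f in sorted(plan.assignment.items()):
        r = by_key.get(key)
        if r is None:
            continue
        models = r.model_paths or {m: None for m in range(1, N_MODELS + 1)}
        if f == fold:
            if 1 not in models:
                raise DatasetError(f"pair {key} lacks model 1 for testing")
            test.append((key, 1, models[1]))
        else:
            if len(models) < N_MODELS:
                logger.warning("pair %s has only %d models for training",
                               key, len(models))
            for m in sorted(models):
                train.append((key, m, models[m]))
    return train, test
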