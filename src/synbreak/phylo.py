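"""Phylogenetic classification of breakpoint groups by maximum likelihood.

Each cross-species breakpoint group carries an observation pattern over the
non-reference species (present / absent / unknown).  A rearrangement on a
branch of the species tree predicts a deterministic pattern: a species is
expected to observe the breakpoint against the reference iff removing that
branch disconnects it from the reference leaf.  A simple two-parameter
error model turns predictions into likelihoods:

    P(present | expected)     = 1 - beta      (detection)
    P(absent  | expected)     = beta          (missed detection)
    P(present | not expected) = alpha         (assembly error / homoplasy)
    P(absent  | not expected) = 1 - alpha

Unknown observations are uninformative and contribute a factor of 1.

Branches that predict identical patterns are indistinguishable from overlap
data against a single reference (e.g. the two edges incident to a
bifurcating root, or any edge on the reference lineage vs its complement),
so classification operates on pattern-equivalence classes of branches.  The
likelihood ratio between the best and second-best class decides between a
confident EBR call and an *uncertain* breakpoint.  Reference-lineage events
(the all-species pattern) are reported on the terminal reference branch:
deeper placement along the reference path is unidentifiable with a single
reference genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

#: Log-likelihood differences below this are treated as exact ties.
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ErrorModel:
    """Free parameters of the breakpoint observation model."""

    alpha: float = 0.02
    beta: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not (0.0 < self.beta < 0.5):
            raise ValueError(f"beta must be in (0, 0.5), got {self.beta}")

    def log_prob(self, observed: str, expected: int) -> float:
        if observed == UNKNOWN:
            return 0.0
        if expected:
            p = 1.0 - self.beta if observed == PRESENT else self.beta
        else:
            p = self.alpha if observed == PRESENT else 1.0 - self.alpha
        return math.log(p)


class Phylogeny:
    """A rooted species tree with identifiable branches.

    Every edge except the root's own edge is a branch; a branch is
    identified by the sorted, ``|``-joined labels of the leaves below it
    (e.g. ``"A|B"``).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf label(s): {', '.join(dupes)}")
        self.leaves: frozenset[str] = frozenset(leaves)
        self._branches: dict[str, frozenset[str]] = {}
        self._branch_lengths: dict[str, float | None] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue  # root edge excluded
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            bid = branch_id(clade)
            self._branches[bid] = clade
            self._branch_lengths[bid] = node.edge.length

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise ValueError(f"unparseable Newick tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_file(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- branch access ------------------------------------------------
    @property
    def branch_ids(self) -> list[str]:
        return sorted(self._branches)

    def clade(self, bid: str) -> frozenset[str]:
        if bid not in self._branches:
            raise KeyError(f"branch {bid!r} not in tree")
        return self._branches[bid]

    def branch_length(self, bid: str) -> float | None:
        return self._branch_lengths[bid]

    def expected_pattern(self, bid: str, reference: str) -> dict[str, int]:
        """Leaves predicted to observe a breakpoint for an event on ``bid``.

        A leaf maps to 1 iff removing the branch disconnects it from the
        reference leaf; the reference itself always maps to 0.
        """
        if reference not in self.leaves:
            raise ValueError(f"reference {reference!r} is not a leaf")
        clade = self.clade(bid)
        ones = (self.leaves - clade) if reference in clade else clade
        return {leaf: int(leaf in ones and leaf != reference) for leaf in sorted(self.leaves)}

    def classification_branch_id(self, bid: str, reference: str) -> str:
        """Canonical reportable branch for ``bid``'s pattern-equivalence class."""
        pattern = self.expected_pattern(bid, reference)
        ones = frozenset(l for l, v in pattern.items() if v)
        if ones == self.leaves - {reference}:
            return branch_id(frozenset({reference}))
        rep = branch_id(ones)
        return rep if rep in self._branches else bid


def branch_id(clade: frozenset[str] | set[str]) -> str:
    return "|".join(sorted(clade))


@dataclass
class ClassificationResult:
    group_id: str
    log_likelihood: dict[str, float]
    best_branch: str
    lr: float
    status: str  # "EBR" or "uncertain"
    lr_threshold: float
    second_branch: str | None = None
    notes: str = field(default="")

    @property
    def is_ebr(self) -> bool:
        return self.status == "EBR"


def branch_log_likelihood(
    pattern: Mapping[str, str],
    bid: str,
    phylo: Phylogeny,
    reference: str,
    error_model: ErrorModel,
) -> float:
    """Log-likelihood of the observed pattern under an event on branch ``bid``."""
    expected = phylo.expected_pattern(bid, reference)
    total = 0.0
    for leaf, obs in pattern.items():
        if leaf == reference:
            continue
        if leaf not in expected:
            raise ValueError(f"species {leaf!r} is not a leaf of the tree")
        if obs not in (PRESENT, ABSENT, UNKNOWN):
            raise ValueError(f"bad observation {obs!r} for {leaf!r}")
        total += error_model.log_prob(obs, expected[leaf])
    return total


def classify(
    pattern: Mapping[str, str],
    phylo: Phylogeny,
    reference: str,
    error_model: ErrorModel | None = None,
    lr_threshold: float = 10.0,
    group_id: str = "",
) -> ClassificationResult:
    """Assign an observation pattern to the most likely branch.

    Evaluates the likelihood of every branch, collapses branches with
    identical expected patterns into one hypothesis class, and compares the
    best against the second-best class.  Status is ``EBR`` iff the
    likelihood ratio reaches ``lr_threshold``; exact ties are *uncertain*.
    """
    error_model = error_model or ErrorModel()
    non_ref = phylo.leaves - {reference}
    extra = set(pattern) - phylo.leaves
    if extra:
        raise ValueError(f"pattern species not in tree: {sorted(extra)}")
    missing = non_ref - set(pattern)
    if missing:
        raise ValueError(f"pattern missing species: {sorted(missing)}")
    if not any(pattern[s] == PRESENT for s in non_ref):
        # no signal at all: still classify, but it can never be confident
        pass

    log_l: dict[str, float] = {}
    classes: dict[tuple[int, ...], dict] = {}
    for bid in phylo.branch_ids:
        expected = phylo.expected_pattern(bid, reference)
        key = tuple(expected[leaf] for leaf in sorted(phylo.leaves))
        ll = branch_log_likelihood(pattern, bid, phylo, reference, error_model)
        log_l[bid] = ll
        cls = classes.setdefault(key, {"logL": ll, "members": []})
        cls["members"].append(bid)

    ref_terminal = branch_id(frozenset({reference}))
    ranked = []
    for key, cls in classes.items():
        ones = frozenset(
            leaf for leaf, v in zip(sorted(phylo.leaves), key) if v
        )
        if ones == non_ref and ref_terminal in phylo.branch_ids:
            rep = ref_terminal
        else:
            rep = branch_id(ones) if branch_id(ones) in phylo.branch_ids else min(cls["members"])
        ranked.append((cls["logL"], rep))
    # deterministic order: by likelihood desc, then branch id; exact ties at
    # the top resolve to the smallest branch id so float jitter in the
    # log-sum cannot flip the reported branch
    ranked.sort(key=lambda t: (-t[0], t[1]))
    best_ll = ranked[0][0]
    best = min(rep for ll, rep in ranked if best_ll - ll <= _TIE_TOL)
    ranked = [(best_ll, best)] + [t for t in ranked if t[1] != best]
    if len(ranked) == 1:
        lr = math.inf
        second = None
    else:
        second_ll, second = ranked[1]
        diff = best_ll - second_ll
        lr = math.exp(diff) if diff < 700 else math.inf
    tied = second is not None and abs(best_ll - ranked[1][0]) <= _TIE_TOL
    status = "EBR" if (not tied and lr >= lr_threshold) else "uncertain"
    return ClassificationResult(
        group_id=group_id,
        log_likelihood=log_l,
        best_branch=best,
        lr=max(lr, 1.0) if math.isfinite(lr) else lr,
        status=status,
        lr_threshold=lr_threshold,
        second_branch=second,
    )
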