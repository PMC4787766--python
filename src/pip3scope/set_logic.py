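"""Venn-region gene sets and the direction-coherence ("PIP3 logic") filter.

The wild-type analysis overlaps three DE sets — genes affected by the
basal activity of PI3K (inhibitor without EGF, 300 vs 0 min), by the
EGF-induced activity of PI3K (inhibitor vs WT time courses under EGF),
and all EGF-dependent genes in WT — into labelled sets 1–4.  The mutant
analysis overlaps the two chronic mutant contrasts, the combined induced
contrast and EGF dependence into sets A–H.  The prose definitions do not
pin every Venn region down, so the label→pattern mapping is configuration
with defaults matching the published descriptions, and the full region
partition is always emitted so any alternative reading can be recovered.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: Comparison names consumed by the coherence filter, with the direction
#: each must take for a gene to count as coherently *up*-regulated by PIP3:
#: up in both activating mutants (chronic and induced contrasts), down
#: under the PI3Kalpha inhibitor with or without EGF.
COHERENCE_COMPARISONS = {
    "chronic_pten": +1,
    "chronic_pik3ca": +1,
    "a66_vs_wt": -1,
    "a66_noegf": -1,
    "induced_pten": +1,
    "induced_pik3ca": +1,
}


def venn_regions(named_sets: dict[str, set[str]], universe: set[str] | None = None):
    """Exact partition of the union into the 2^n - 1 non-empty-pattern regions.

    Keys of the result are tuples of booleans aligned with the sorted set
    labels; values are the gene sets.  Regions are pairwise disjoint and
    their union equals the union of the inputs.
    """
    labels = sorted(named_sets)
    if universe is not None:
        for lab in labels:
            stray = named_sets[lab] - universe
            if stray:
                raise ValueError(f"set {lab!r} has members outside the universe")
    union = set().union(*(named_sets[lab] for lab in labels)) if labels else set()
    regions = {
        pattern: set()
        for pattern in itertools.product([False, True], repeat=len(labels))
        if any(pattern)
    }
    for gene in union:
        pattern = tuple(gene in named_sets[lab] for lab in labels)
        regions[pattern].add(gene)
    return {"labels": labels, "regions": regions}


def build_wt_sets(
    basal: set[str], induced: set[str], egf_dep: set[str]
) -> dict[str, set[str]]:
    """Sets 1–4 of the wild-type analysis (plus the full region partition).

    Defaults: set1 = basal ∩ egf_dep \\ induced (basal activity of PI3K
    plus PI3K-independent EGF pathways); set2 = basal only; set3 =
    basal ∩ induced (both activities, regardless of EGF dependence);
    set4 = induced ∩ egf_dep \\ basal (EGF-induced activity only).
    """
    out = {
        "set1": (basal & egf_dep) - induced,
        "set2": basal - induced - egf_dep,
        "set3": basal & induced,
        "set4": (induced & egf_dep) - basal,
    }
    out["_regions"] = venn_regions(
        {"basal": basal, "induced": induced, "egf_dep": egf_dep}
    )
    return out


def build_mutant_sets(
    chronic_pten: set[str],
    chronic_pik3ca: set[str],
    induced_combined: set[str],
    egf_dep: set[str],
) -> dict[str, set[str]]:
    """Sets A–H of the mutant analysis (plus the full region partition).

    A/B: affected by both chronic contrasts; C/D: PIK3CA-only; E/F:
    PTEN-only; G/H: no chronic effect but in the combined induced set.
    The first of each pair is the EGF-dependent half, the second the
    EGF-insensitive half.
    """
    both = chronic_pten & chronic_pik3ca
    pik_only = chronic_pik3ca - chronic_pten
    pten_only = chronic_pten - chronic_pik3ca
    neither_chronic = induced_combined - chronic_pten - chronic_pik3ca
    out = {
        "A": both & egf_dep,
        "B": both - egf_dep,
        "C": pik_only & egf_dep,
        "D": pik_only - egf_dep,
        "E": pten_only & egf_dep,
        "F": pten_only - egf_dep,
        "G": neither_chronic & egf_dep,
        "H": neither_chronic - egf_dep,
    }
    out["_regions"] = venn_regions(
        {
            "chronic_pten": chronic_pten,
            "chronic_pik3ca": chronic_pik3ca,
            "induced": induced_combined,
            "egf_dep": egf_dep,
        }
    )
    return out


def signed_outcomes(results: dict[str, "DEResult"]) -> pd.DataFrame:
    """genes x comparisons matrix of direction signs (0 = not significant).

    Direction for LRT designs is the sign of the maximal-magnitude log2
    fold change across levels, as reported by the DE engine.
    """
    cols = {}
    for name, res in results.items():
        cols[name] = res.signed_outcome()
    return pd.DataFrame(cols)


def coherence_filter(outcomes: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes changing coherently with the PIP3 perturbation logic.

    ``outcomes`` must hold a signed column for every comparison in
    :data:`COHERENCE_COMPARISONS`.  coherent_up genes are significant in
    all six with signs (+, +, -, -, +, +); coherent_down is the mirror.
    """
    missing = [c for c in COHERENCE_COMPARISONS if c not in outcomes.columns]
    if missing:
        raise ValueError(f"missing comparison column(s) {missing}")
    signs = outcomes[list(COHERENCE_COMPARISONS)].to_numpy()
    expected = np.array([COHERENCE_COMPARISONS[c] for c in COHERENCE_COMPARISONS])
    up = (signs == expected[None, :]).all(axis=1)
    down = (signs == -expected[None, :]).all(axis=1)
    idx = outcomes.index
    return set(idx[up]), set(idx[down])
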