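"""The structured multi-family pedigree used by the simulation study.

Each family contains 21 individuals across three generations:

* Gen1 (founders): one sire mated to 5 unrelated dams;
* Gen2: each sire x dam pair produces 2 full-sib offspring (10 total);
* Gen3: the two full sibs of each pair mate to produce 1 inbred offspring
  (5 total).

Families are mutually unrelated. With bivalent meiosis and no double
reduction, the pedigree expectations of the relatedness coefficient
r = sqrt(psi_h psi_i) theta (and r_ii = 1 + (psi-1) F on the diagonal) are
ploidy-free: Gen3 self-relatedness 1.25, parent-offspring (Gen2-Gen3) 0.75,
parent-offspring (Gen1-Gen2) / full sibs / grandparent-offspring 0.5, and
half sibs / half cousins / pibling-half-nibling 0.25.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

__all__ = ["build_pedigree", "classify_pairs", "PAIR_CLASSES", "EXPECTED_RELATEDNESS"]

#: Relationship classes in display order. "SR" = self-relatedness (diagonal),
#: "PO" = parent-offspring, "FS" = full sibs, "GO" = grandparent-offspring,
#: "HS" = half sibs, "HC" = half cousins, "PHN" = pibling-half-nibling,
#: "UR" = unrelated.
PAIR_CLASSES = [
    "SR (G1)",
    "SR (G2)",
    "SR (G3)",
    "PO (G2-G3)",
    "PO (G1-G2)",
    "FS (G2)",
    "GO (G1-G3)",
    "HS (G2)",
    "HC (G3)",
    "PHN (G2-G3)",
    "UR",
]

#: Pedigree expectation of each class's relatedness coefficient (any ploidy,
#: bivalent meiosis, no double reduction).
EXPECTED_RELATEDNESS = {
    "SR (G1)": 1.0,
    "SR (G2)": 1.0,
    "SR (G3)": 1.25,
    "PO (G2-G3)": 0.75,
    "PO (G1-G2)": 0.5,
    "FS (G2)": 0.5,
    "GO (G1-G3)": 0.5,
    "HS (G2)": 0.25,
    "HC (G3)": 0.25,
    "PHN (G2-G3)": 0.25,
    "UR": 0.0,
}


def build_pedigree(n_families: int) -> pd.DataFrame:
    """Construct the pedigree table for ``n_families`` independent families.

    Returns a DataFrame with columns ``id``, ``sire``, ``dam`` (None for
    founders), ``generation`` in {Gen1, Gen2, Gen3} and ``family`` (0-based
    index), parents always preceding offspring.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rows = []
    for f in range(n_families):
        tag = f"F{f + 1:02d}"
        sire = f"{tag}_S"
        rows.append((sire, None, None, "Gen1", f))
        for k in range(1, 6):
            rows.append((f"{tag}_D{k}", None, None, "Gen1", f))
        for k in range(1, 6):
            dam = f"{tag}_D{k}"
            for c in "ab":
                rows.append((f"{tag}_P{k}{c}", sire, dam, "Gen2", f))
        for k in range(1, 6):
            rows.append((f"{tag}_I{k}", f"{tag}_P{k}a", f"{tag}_P{k}b", "Gen3", f))
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "family"])


def classify_pairs(ped: pd.DataFrame) -> pd.DataFrame:
    """Assign every (unordered, including self) pair to a relationship class.

    Classification is rule-based from the pedigree records themselves
    (parent and grandparent sets), not from naming conventions, so it also
    serves as a structural check on the pedigree. Returns a DataFrame with
    columns ``id1``, ``id2``, ``cls``; self pairs carry the SR classes.
    """
    ids = list(ped["id"])
    gen = dict(zip(ped["id"], ped["generation"]))
    fam = dict(zip(ped["id"], ped["family"]))
    parents = {
        r.id: {x for x in (r.sire, r.dam) if x is not None}
        for r in ped.itertuples()
    }
    grandparents = {i: set().union(*(parents[p] for p in parents[i])) if parents[i] else set() for i in ids}

    def classify(a: str, b: str) -> str:
        if a == b:
            return {"Gen1": "SR (G1)", "Gen2": "SR (G2)", "Gen3": "SR (G3)"}[gen[a]]
        if fam[a] != fam[b]:
            return "UR"
        ga, gb = gen[a], gen[b]
        if ga > gb:  # order so a is the earlier generation
            a, b, ga, gb = b, a, gb, ga
        if ga == "Gen1" and gb == "Gen1":
            return "UR"
        if ga == "Gen1" and gb == "Gen2":
            return "PO (G1-G2)" if a in parents[b] else "UR"
        if ga == "Gen1" and gb == "Gen3":
            return "GO (G1-G3)" if a in grandparents[b] else "UR"
        if ga == "Gen2" and gb == "Gen2":
            shared = len(parents[a] & parents[b])
            if shared == 2:
                return "FS (G2)"
            if shared == 1:
                return "HS (G2)"
            raise ValueError(f"unexpected Gen2 pair structure: {a}, {b}")
        if ga == "Gen2" and gb == "Gen3":
            return "PO (G2-G3)" if a in parents[b] else "PHN (G2-G3)"
        if ga == "Gen3" and gb == "Gen3":
            return "HC (G3)"
        raise ValueError(f"cannot classify pair ({a}, {b})")

    recs = [(i, i, classify(i, i)) for i in ids]
    recs += [(a, b, classify(a, b)) for a, b in combinations(ids, 2)]
    return pd.DataFrame(recs, columns=["id1", "id2", "cls"])
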