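"""Regenerate the packaged fixture data files (deterministic).

Writes, into src/divtime/data/:
  - four_species_table.csv   the 16-row full pairwise example table
  - catharus_synthetic.nwk   synthetic Yule tree, 12 tips, crown 4.73 MY
  - malurus_synthetic.nwk    synthetic Yule tree, 11 tips, crown 9.0 MY

Run from the repository root:  python scripts/make_fixtures.py
"""

from __future__ import annotations

from pathlib import Path

from divtime.divergence_data import (
    DivergenceMatrix,
    DivergencePair,
    PairwiseTable,
    TableMode,
    write_table_csv,
)
from divtime.fixture_factory import (
    CATHARUS_CROWN_MY,
    CATHARUS_SPECIES,
    CATHARUS_TREE_SEED,
    MALURUS_CROWN_MY,
    MALURUS_SPECIES,
    MALURUS_TREE_SEED,
    YuleSimConfig,
    simulate_yule_tree,
)
from divtime.timetrees import write_newick

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "divtime" / "data"

SPECIES = [
    "Passerina amoena",        # Lazuli bunting
    "Corythornis cristatus",   # Malachite kingfisher
    "Chalcomitra amethystine", # Amethyst sunbird
    "Chrysococcyx cupreus",    # Emerald cuckoo
]

# (time, ci_low, ci_high, studies) per unordered pair, indexed by SPECIES pos
PAIR_DATA = {
    (0, 1): (70.0, 64.5, 80.0, 16),
    (0, 2): (27.6, 25.4, 38.1, 5),
    (0, 3): (80.0, 73.7, 97.3, 3),
    (1, 2): (70.0, 64.5, 80.0, 16),
    (1, 3): (80.0, 73.7, 97.3, 3),
    (2, 3): (80.0, 73.7, 97.3, 3),
}


def four_species_table() -> PairwiseTable:
    rows = []
    for i, a in enumerate(SPECIES):
        for j, b in enumerate(SPECIES):
            if i == j:
                rows.append(DivergencePair(a, b, 0.0))
                continue
            t, lo, hi, k = PAIR_DATA[(min(i, j), max(i, j))]
            rows.append(
                DivergencePair(a, b, t, ci_low_mya=lo, ci_high_mya=hi, n_studies=k)
            )
    return PairwiseTable(species=SPECIES, rows=rows, mode=TableMode.FULL)


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_table_csv(four_species_table(), DATA_DIR / "four_species_table.csv")

    for fname, n, crown, seed, labels in [
        (
            "catharus_synthetic.nwk",
            12,
            CATHARUS_CROWN_MY,
            CATHARUS_TREE_SEED,
            CATHARUS_SPECIES,
        ),
        (
            "malurus_synthetic.nwk",
            11,
            MALURUS_CROWN_MY,
            MALURUS_TREE_SEED,
            MALURUS_SPECIES,
        ),
    ]:
        tree = simulate_yule_tree(
            YuleSimConfig(
                n_tips=n, crown_age_mya=crown, seed=seed, labels=tuple(labels)
            )
        )
        (DATA_DIR / fname).write_text(write_newick(tree) + "\n", encoding="utf-8")
    print(f"fixtures written to {DATA_DIR}")


if __name__ == "__main__":
    main()
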