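"""Nested paternal half-sib crossing designs.

Each sire (pollen donor) is crossed to a fixed number of unique dams
(pollen recipients); each cross contributes a fixed number of offspring.
Offspring are allocated to field blocks in a balanced round-robin so
families are spread evenly across blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import DESIGN_COLUMNS


def make_design(
    n_populations: int,
    n_sires: int,
    n_dams_per_sire: int,
    n_offspring_per_dam: int,
    n_blocks: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the design table for a nested half-sib experiment.

    Returns one row per planned individual with population, block, sire,
    dam and individual labels.  The layout is fully deterministic: block
    assignment is a round-robin within each sire-dam family, with the
    starting block rotated by family index so blocks stay balanced when
    family size is not a multiple of ``n_blocks``.  ``seed`` is accepted
    for interface symmetry with the stochastic generators.
    """
    params = {
        "n_populations": n_populations,
        "n_sires": n_sires,
        "n_dams_per_sire": n_dams_per_sire,
        "n_offspring_per_dam": n_offspring_per_dam,
        "n_blocks": n_blocks,
    }
    for name, value in params.items():
        if int(value) != value or value < 1:
            raise ValueError(f"{name} must be a positive integer, got {value!r}")

    rows: dict[str, list] = {c: [] for c in DESIGN_COLUMNS}
    family = 0
    for ip in range(n_populations):
        pop = f"P{ip + 1}"
        for js in range(n_sires):
            sire = f"{pop}_S{js + 1:03d}"
            for kd in range(n_dams_per_sire):
                dam = f"{sire}_D{kd + 1}"
                for o in range(n_offspring_per_dam):
                    block = (family + o) % n_blocks + 1
                    rows["population"].append(pop)
                    rows["block"].append(str(block))
                    rows["sire"].append(sire)
                    rows["dam"].append(dam)
                    rows["individual"].append(f"{dam}_O{o + 1}")
                family += 1
    table = pd.DataFrame(rows)
    return table


def design_summary(design: pd.DataFrame) -> dict:
    """Counts of populations, families (sire-dam crosses) and individuals."""
    return {
        "n_populations": design["population"].nunique(),
        "n_sires": design["sire"].nunique(),
        "n_families": design.groupby(["sire", "dam"]).ngroups,
        "n_individuals": len(design),
    }
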