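"""Database census registry and synthetic fixture generation.

The registry transcribes the published per-class census of the annotated
nanomaterial database (705 structures over 11 material classes) and the
per-endpoint dataset memberships (logP, zeta potential, cellular uptake).

The synthetic recipe builds small ligand-decorated metal particles through the
regular builder + descriptor pipeline and plants a linear structure–activity
signal on a handful of descriptor columns, providing a desk-scale dataset with
a known ground truth for exercising the modeling protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import CoreSpec, LigandSpec, build_core, graft_ligands
from .descriptors import DEFAULT_ATOM_BUDGET, compute_descriptors, filter_descriptors
from .errors import AtomBudgetError, NanotessError
from .modeling import EndpointDataset

# Published database census: material class -> number of annotated structures.
REGISTRY_COUNTS = {
    "GNP": 414, "AgNP": 17, "PtNP": 12, "PdNP": 12, "CNT": 80, "C60": 48,
    "QD": 34, "MONP": 32, "DnaNP": 21, "Dendrimer": 11, "CPNT": 24,
}

# Endpoint dataset memberships: endpoint -> {material class: count}.
ENDPOINT_MEMBERSHIP = {
    "logP": {"GNP": 123, "PtNP": 12, "PdNP": 12},
    "zeta_potential": {
        "GNP": 148, "AgNP": 6, "PtNP": 12, "PdNP": 12,
        "MONP": 8, "QD": 24, "Dendrimer": 3,
    },
    "cellular_uptake": {"GNP": 71},
}

# Endpoint units: logP unitless; zeta potential mV (water, pH 7);
# cellular uptake log10 g per cell (A549 cells).
ENDPOINT_UNITS = {
    "logP": "log10(octanol/water partition)",
    "zeta_potential": "mV",
    "cellular_uptake": "log10 g/cell",
}


def registry_counts() -> pd.DataFrame:
    """Census table: per-class structure counts and endpoint memberships."""
    classes = list(REGISTRY_COUNTS)
    frame = pd.DataFrame(index=classes)
    frame["structures"] = [REGISTRY_COUNTS[c] for c in classes]
    for endpoint, members in ENDPOINT_MEMBERSHIP.items():
        frame[endpoint] = [members.get(c, 0) for c in classes]
    return frame


@dataclass(frozen=True)
class SyntheticRecipe:
    """Recipe R1: small grafted particles with a planted linear endpoint.

    The endpoint is y = beta . z + eps where z are ``n_signal`` min-max scaled
    descriptor columns and eps ~ Normal(0, sigma^2) with the signal variance
    fixed at ``signal_to_noise_var`` times the noise variance.
    """

    n: int = 150
    materials: tuple[str, ...] = ("fcc-Au", "fcc-Ag", "fcc-Pt", "fcc-Pd")
    diameter_range_nm: tuple[float, float] = (1.2, 2.2)
    ligand_pool: tuple[str, ...] = ("CCS", "OCCS", "NCCS", "CCCCS", "OC(=O)CS")
    ligand_count_range: tuple[int, int] = (3, 12)
    n_signal: int = 5
    signal_to_noise_var: float = 4.0
    endpoint: str = "logP"
    seed: int = 0
    atom_budget: int = DEFAULT_ATOM_BUDGET

    def __post_init__(self):
        if self.n < 10:
            raise NanotessError("recipe needs n >= 10")
        if self.signal_to_noise_var <= 0:
            raise NanotessError("signal/noise variance ratio must be positive")


def _estimate_atoms(diameter_nm: float) -> int:
    # fcc metals: ~60 atoms per nm^3 is a generous upper bound
    volume = 4.0 / 3.0 * np.pi * (diameter_nm * 10 / 2) ** 3
    return int(volume / 15.0) + 1


def build_fixture_structures(recipe: SyntheticRecipe) -> list:
    """Build the recipe's particle set (deterministic under the recipe seed)."""
    worst = _estimate_atoms(recipe.diameter_range_nm[1]) + 40 * recipe.ligand_count_range[1]
    if worst > recipe.atom_budget:
        raise AtomBudgetError(
            f"recipe may produce ~{worst} atoms, above the budget {recipe.atom_budget}"
        )
    rng = np.random.default_rng(recipe.seed)
    structures = []
    for i in range(recipe.n):
        material = recipe.materials[int(rng.integers(len(recipe.materials)))]
        diameter = float(rng.uniform(*recipe.diameter_range_nm))
        smiles = recipe.ligand_pool[int(rng.integers(len(recipe.ligand_pool)))]
        count = int(rng.integers(recipe.ligand_count_range[0],
                                 recipe.ligand_count_range[1] + 1))
        core = build_core(CoreSpec(
            material=material, shape="sphere", diameter_nm=round(diameter, 3),
            identifier=f"SYN{i + 1:03d}",
        ))
        seed_i = int(rng.integers(2**31))
        structures.append(
            graft_ligands(core, [LigandSpec(smiles, count)], seed=seed_i)
        )
    return structures


def generate_fixture_set(recipe: SyntheticRecipe = SyntheticRecipe()):
    """Build structures, compute descriptors, and plant the endpoint signal.

    Returns ``(structures, dataset)`` where the dataset's X is the
    variance-filtered descriptor matrix and y carries the planted signal.
    Fully reproducible from the recipe's seed.
    """
    structures = build_fixture_structures(recipe)
    matrix = pd.DataFrame(
        [compute_descriptors(s, atom_budget=recipe.atom_budget).values for s in structures]
    )
    filtered, kept, _ = filter_descriptors(matrix)

    rng = np.random.default_rng(recipe.seed + 1)
    # scale to [0,1] so the planted coefficients act on comparable columns
    z = (filtered - filtered.min()) / (filtered.max() - filtered.min())
    # candidate signal columns: well-spread, mutually non-duplicate
    stds = z.std(axis=0)
    candidates = [c for c in z.columns if stds[c] >= 0.15]
    if len(candidates) < recipe.n_signal:
        candidates = list(stds.sort_values(ascending=False).index)
    chosen: list = []
    for c in rng.permutation(np.array(candidates, dtype=object)):
        if all(abs(z[c].corr(z[c2])) < 0.9 for c2 in chosen):
            chosen.append(c)
        if len(chosen) == recipe.n_signal:
            break
    beta = rng.normal(0.0, 1.0, size=len(chosen))
    signal = z[chosen].to_numpy() @ beta
    sigma = float(np.std(signal)) / np.sqrt(recipe.signal_to_noise_var)
    noise = rng.normal(0.0, sigma, size=recipe.n)
    y = pd.Series(signal + noise, index=filtered.index, name=recipe.endpoint)

    dataset = EndpointDataset(
        X=filtered, y=y, endpoint=recipe.endpoint,
        metadata={
            "recipe": "R1", "seed": recipe.seed, "sigma": sigma,
            "signal_columns": list(chosen), "beta": beta.tolist(),
            "units": ENDPOINT_UNITS.get(recipe.endpoint, ""),
        },
    )
    return structures, dataset
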