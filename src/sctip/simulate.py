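"""Synthetic single-cell UMI time courses with a controllable attractor transition.

Each cell carries a latent state ``s`` in [0, 1] drawn from a Beta
distribution whose mean moves monotonically across time points and whose
concentration collapses at the designated transition time, broadening the
state distribution there.  Two antagonistic gene programs read the state
out as ``1 - s`` and ``s``; counts are negative-binomial with per-cell
library-size factors and optional per-entry lognormal expression noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import CellAnnotation, CountMatrix, GeneAnnotation


class SimulationConfigError(ValueError):
    """Raised before any sampling when a configuration is invalid."""


@dataclass
class SimulationConfig:
    n_time_points: int = 5
    transition_index: int = 2
    cells_per_time: int = 200
    n_program_a: int = 60
    n_program_b: int = 60
    n_housekeeping: int = 40
    n_mito: int = 37
    n_tf_per_program: int = 8
    base_mean: float = 50.0
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    stable_beta: float = 60.0
    transition_beta: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0
    #: optional per-time override of the latent-state mean (testing hook)
    latent_means: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_time_points < 3:
            raise SimulationConfigError("need at least 3 time points")
        if not (0 <= self.transition_index < self.n_time_points):
            raise SimulationConfigError("transition_index out of range")
        for name in (
            "cells_per_time",
            "n_program_a",
            "n_program_b",
            "n_housekeeping",
            "n_mito",
        ):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive")
        if self.n_tf_per_program < 1 or self.n_tf_per_program > min(
            self.n_program_a, self.n_program_b
        ):
            raise SimulationConfigError("n_tf_per_program exceeds program size")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise SimulationConfigError("base_mean and dispersion must be positive")
        if self.libsize_sigma < 0 or self.noise_sd < 0:
            raise SimulationConfigError("sigmas must be non-negative")
        if self.stable_beta <= 0 or self.transition_beta <= 0:
            raise SimulationConfigError("Beta concentrations must be positive")
        if not self.transition_beta < self.stable_beta:
            raise SimulationConfigError(
                "transition_beta must be smaller than stable_beta"
            )
        if self.latent_means is not None and len(self.latent_means) != self.n_time_points:
            raise SimulationConfigError("latent_means length mismatch")


@dataclass
class SimulationTruth:
    """Ground truth retained for parameter-recovery tests."""

    latent_state: pd.Series  # cell_id -> s
    gene_program: pd.Series  # gene_id -> {program_a, program_b, housekeeping, mito}
    tf_a: list[str]
    tf_b: list[str]
    transition_index: int
    time_levels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "latent_state": self.latent_state.to_dict(),
            "gene_program": self.gene_program.to_dict(),
            "tf_a": self.tf_a,
            "tf_b": self.tf_b,
            "transition_index": self.transition_index,
            "time_levels": list(self.time_levels),
        }


def latent_state_means(n_time_points: int, transition_index: int) -> np.ndarray:
    """Monotone interpolation of latent-state means, pinned to 0.5 at t*."""
    m = np.linspace(0.05, 0.95, n_time_points)
    m[transition_index] = 0.5
    return m


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean=mu, size=dispersion); variance = mu + mu^2/size.  inf size = Poisson."""
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _expression_noise(
    rng: np.random.Generator, shape: tuple[int, int], noise_sd: float
) -> np.ndarray:
    if noise_sd == 0:
        return np.ones(shape)
    return rng.lognormal(0.0, noise_sd, size=shape)


def simulate_time_course(
    config: SimulationConfig,
) -> tuple[CountMatrix, CellAnnotation, GeneAnnotation, SimulationTruth]:
    """Sample a full time course.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tstar = config.transition_index
    n_t = config.n_time_points
    means = (
        np.asarray(config.latent_means, dtype=float)
        if config.latent_means is not None
        else latent_state_means(n_t, tstar)
    )
    time_levels = tuple(f"T{t}" for t in range(n_t))

    gene_ids, programs, gann = _make_gene_panel(config)
    a_rows = programs == "program_a"
    b_rows = programs == "program_b"
    hk_rows = programs == "housekeeping"
    mt_rows = programs == "mito"
    n_genes = len(gene_ids)

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    cell_time: list[str] = []
    latent: list[float] = []
    for t in range(n_t):
        # the explicit latent_means override pins every time point (t*
        # included) to a concentrated Beta around the requested mean
        if t == tstar and config.latent_means is None:
            s = rng.beta(config.transition_beta, config.transition_beta,
                         size=config.cells_per_time)
        else:
            m = float(np.clip(means[t], 1e-6, 1 - 1e-6))
            s = rng.beta(m * config.stable_beta, (1 - m) * config.stable_beta,
                         size=config.cells_per_time)
        base = np.empty((n_genes, config.cells_per_time))
        base[a_rows, :] = config.base_mean * (1.0 - s)[None, :]
        base[b_rows, :] = config.base_mean * s[None, :]
        base[hk_rows, :] = config.base_mean
        base[mt_rows, :] = 0.05 * config.base_mean
        eps = _expression_noise(rng, base.shape, config.noise_sd)
        lib = (
            rng.lognormal(0.0, config.libsize_sigma, size=config.cells_per_time)
            if config.libsize_sigma > 0
            else np.ones(config.cells_per_time)
        )
        mu = base * eps * lib[None, :]
        blocks.append(_nb_counts(rng, mu, config.dispersion))
        cell_ids.extend(f"{time_levels[t]}_c{i:04d}" for i in range(config.cells_per_time))
        cell_time.extend([time_levels[t]] * config.cells_per_time)
        latent.extend(s.tolist())

    values = np.concatenate(blocks, axis=1)
    cm = CountMatrix(values, gene_ids, cell_ids)
    cells = CellAnnotation.from_frame(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "time_point": cell_time,
                "cluster": cell_time,
                "condition": ["base"] * len(cell_ids),
            }
        ),
        time_order=time_levels,
    )
    truth = SimulationTruth(
        latent_state=pd.Series(latent, index=cell_ids, name="s"),
        gene_program=pd.Series(programs, index=gene_ids, name="program"),
        tf_a=gann.flagged("is_tf")[: config.n_tf_per_program],
        tf_b=[g for g in gann.flagged("is_tf") if g.startswith("progB")],
        transition_index=tstar,
        time_levels=time_levels,
    )
    return cm, cells, gann, truth


def _make_gene_panel(
    config: SimulationConfig,
) -> tuple[list[str], np.ndarray, GeneAnnotation]:
    gene_ids: list[str] = []
    programs: list[str] = []
    for i in range(config.n_program_a):
        gene_ids.append(f"progA_{i:03d}")
        programs.append("program_a")
    for i in range(config.n_program_b):
        gene_ids.append(f"progB_{i:03d}")
        programs.append("program_b")
    for i in range(config.n_housekeeping):
        gene_ids.append(f"hk_{i:03d}")
        programs.append("housekeeping")
    for i in range(config.n_mito):
        gene_ids.append(f"mt-{i:02d}")
        programs.append("mito")
    programs_arr = np.asarray(programs)
    tf = np.zeros(len(gene_ids), dtype=bool)
    tf[: config.n_tf_per_program] = True  # first TFs of program A
    tf[config.n_program_a : config.n_program_a + config.n_tf_per_program] = True
    gann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_mitochondrial": programs_arr == "mito",
                "is_housekeeping": programs_arr == "housekeeping",
                "is_tf": tf,
                "is_ligand": False,
                "is_receptor": False,
            }
        )
    )
    return gene_ids, programs_arr, gann


def simulate_clusters(
    n_clusters: int = 4,
    cells_per_cluster: int = 80,
    genes_per_cluster: int = 30,
    n_shared: int = 40,
    base_mean: float = 30.0,
    off_target_fraction: float = 0.05,
    dispersion: float = 2.0,
    libsize_sigma: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, CellAnnotation, GeneAnnotation]:
    """Discrete cell clusters with exclusive marker programs.

    Cluster k expresses its own ``genes_per_cluster`` genes at ``base_mean``
    (``off_target_fraction`` of that elsewhere) on top of a shared
    background; cluster labels are stored in the annotation.  Fixture for
    signature-matching recovery tests.
    """
    if n_clusters < 2:
        raise SimulationConfigError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    gene_ids = [
        f"cl{k}_g{i:03d}" for k in range(n_clusters) for i in range(genes_per_cluster)
    ] + [f"shared_{i:03d}" for i in range(n_shared)]
    n_cells = n_clusters * cells_per_cluster
    labels = [f"K{k}" for k in range(n_clusters) for _ in range(cells_per_cluster)]

    base = np.full((len(gene_ids), n_cells), np.nan)
    for k in range(n_clusters):
        rows = slice(k * genes_per_cluster, (k + 1) * genes_per_cluster)
        in_cluster = np.asarray([lab == f"K{k}" for lab in labels])
        base[rows, :] = np.where(
            in_cluster, base_mean, off_target_fraction * base_mean
        )
    base[n_clusters * genes_per_cluster:, :] = base_mean

    eps = _expression_noise(rng, base.shape, noise_sd)
    lib = (
        rng.lognormal(0.0, libsize_sigma, size=n_cells)
        if libsize_sigma > 0
        else np.ones(n_cells)
    )
    counts = _nb_counts(rng, base * eps * lib[None, :], dispersion)
    cell_ids = [f"K{k}_c{i:04d}" for k in range(n_clusters) for i in range(cells_per_cluster)]
    cm = CountMatrix(counts, gene_ids, cell_ids)
    cells = CellAnnotation.from_frame(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "time_point": ["T0"] * n_cells,
                "cluster": labels,
                "condition": ["base"] * n_cells,
            }
        ),
        time_order=("T0",),
    )
    gann = GeneAnnotation(pd.DataFrame({"gene_id": gene_ids}))
    return cm, cells, gann


# ---------------------------------------------------------------------------
# two-condition ligand/receptor fixture
# ---------------------------------------------------------------------------

@dataclass
class ConditionPairConfig:
    cells_per_condition: int = 500
    sender_fraction: float = 0.5
    n_lr_pairs: int = 5
    n_background: int = 50
    base_mean: float = 20.0
    off_target_fraction: float = 0.05
    dispersion: float = 2.0
    libsize_sigma: float = 0.2
    noise_sd: float = 0.1
    conditions: tuple[str, str] = ("condA", "condB")
    clusters: tuple[str, str] = ("sender", "receiver")
    #: ligand gene id -> fold applied to its mean in the second condition
    ligand_folds: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def ligand_ids(self) -> list[str]:
        return [f"lig_{i:02d}" for i in range(self.n_lr_pairs)]

    def receptor_ids(self) -> list[str]:
        return [f"rec_{i:02d}" for i in range(self.n_lr_pairs)]

    def lr_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.ligand_ids(), self.receptor_ids()))

    def validate(self) -> None:
        if self.cells_per_condition < 2 or self.n_lr_pairs < 1:
            raise SimulationConfigError("need cells and at least one LR pair")
        if not 0 < self.sender_fraction < 1:
            raise SimulationConfigError("sender_fraction must be in (0, 1)")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise SimulationConfigError("need two distinct condition labels")
        if len(self.clusters) < 2:
            raise SimulationConfigError("need at least two clusters")
        ligands = set(self.ligand_ids())
        for g in self.ligand_folds:
            if g not in ligands:
                raise SimulationConfigError(
                    f"fold effect specified for non-ligand gene {g!r}"
                )


def simulate_condition_pair(
    config: ConditionPairConfig,
) -> tuple[CountMatrix, CellAnnotation, GeneAnnotation]:
    """Two-condition dataset with planted ligand fold changes.

    Ligands are expressed mainly in the sender cluster and receptors in the
    receiver cluster; all other structure is exchangeable between the two
    conditions, so with all folds at 1 the conditions are samples from one
    distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    lig_ids = config.ligand_ids()
    rec_ids = config.receptor_ids()
    bg_ids = [f"bg_{i:03d}" for i in range(config.n_background)]
    gene_ids = lig_ids + rec_ids + bg_ids
    n_genes = len(gene_ids)

    n_sender = int(round(config.sender_fraction * config.cells_per_condition))
    n_receiver = config.cells_per_condition - n_sender
    off = config.off_target_fraction

    blocks = []
    cell_ids: list[str] = []
    cell_cluster: list[str] = []
    cell_condition: list[str] = []
    for ci, cond in enumerate(config.conditions):
        cluster_of_cell = [config.clusters[0]] * n_sender + [config.clusters[1]] * n_receiver
        sender_mask = np.asarray([c == config.clusters[0] for c in cluster_of_cell])
        base = np.empty((n_genes, config.cells_per_condition))
        for gi, g in enumerate(lig_ids):
            mean = config.base_mean * (
                config.ligand_folds.get(g, 1.0) if ci == 1 else 1.0
            )
            base[gi, :] = np.where(sender_mask, mean, off * mean)
        for gi, g in enumerate(rec_ids):
            base[len(lig_ids) + gi, :] = np.where(
                sender_mask, off * config.base_mean, config.base_mean
            )
        base[len(lig_ids) + len(rec_ids):, :] = config.base_mean
        eps = _expression_noise(rng, base.shape, config.noise_sd)
        lib = (
            rng.lognormal(0.0, config.libsize_sigma, size=config.cells_per_condition)
            if config.libsize_sigma > 0
            else np.ones(config.cells_per_condition)
        )
        blocks.append(_nb_counts(rng, base * eps * lib[None, :], config.dispersion))
        cell_ids.extend(
            f"{cond}_c{i:04d}" for i in range(config.cells_per_condition)
        )
        cell_cluster.extend(cluster_of_cell)
        cell_condition.extend([cond] * config.cells_per_condition)

    cm = CountMatrix(np.concatenate(blocks, axis=1), gene_ids, cell_ids)
    cells = CellAnnotation.from_frame(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "time_point": ["T0"] * len(cell_ids),
                "cluster": cell_cluster,
                "condition": cell_condition,
            }
        ),
        time_order=("T0",),
    )
    gann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_mitochondrial": False,
                "is_housekeeping": [g.startswith("bg_") for g in gene_ids],
                "is_tf": False,
                "is_ligand": [g.startswith("lig_") for g in gene_ids],
                "is_receptor": [g.startswith("rec_") for g in gene_ids],
            }
        )
    )
    return cm, cells, gann
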