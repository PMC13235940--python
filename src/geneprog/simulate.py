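"""Synthetic multi-donor single-cell data with planted, graph-aligned modules.

The generator emulates the structure the learner assumes: genes organised
into modules that are both co-expressed and densely connected in the
annotation graph, donor-level binary phenotypes inherited by cells, and an
optional fraction of mislabeled cells per donor (cells whose activity is
drawn from the opposite class — the kind of label noise that arises when
individual phenotypes are propagated to heterogeneous cells).

Activity model: each module's per-cell activity is Normal(class mean, 1);
informative modules shift their mean by ``effect_size`` in the positive
class.  A gene's value is exp(activity + Normal(0, noise_sd)), scaled and
Poisson-sampled, giving right-skewed nonnegative counts whose planted
structure is linear after log transform.  Background genes draw independent
activities and join the graph only through ``p_out`` edges and self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import ExpressionDataset
from .graph import GeneGraph

__all__ = ["SimConfig", "SyntheticDataset", "generate"]

_COUNT_SCALE = 10.0  # mean count scale after exponentiation


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    n_genes: int = 300
    n_modules: int = 5
    module_size: int = 20
    n_donors_per_class: int = 8
    cells_per_donor: int = 25
    p_in: float = 0.3
    p_out: float = 0.01
    effect_size: float = 2.0
    informative_modules: tuple[int, ...] | None = None  # None -> first min(3, n_modules)
    cell_label_noise: float = 0.0
    noise_sd: float = 0.5
    train_donor_fraction: float = 0.5
    seed: int = 0

    def informative(self) -> tuple[int, ...]:
        if self.informative_modules is None:
            return tuple(range(min(3, self.n_modules)))
        return tuple(self.informative_modules)

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit in the gene universe")
        for name in ("p_in", "p_out", "cell_label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.0 < self.train_donor_fraction < 1.0:
            raise ValueError("train_donor_fraction must lie in (0, 1)")
        if any(m < 0 or m >= self.n_modules for m in self.informative()):
            raise ValueError("informative_modules out of range")


@dataclass
class SyntheticDataset:
    """Generated expression, annotation graph and planted truth."""

    expression: ExpressionDataset
    graph: GeneGraph
    truth: dict[str, int] = field(repr=False)  # gene -> planted module

    def truth_labels(self, genes: list[str]) -> np.ndarray:
        """Planted module index per gene, -1 for background genes."""
        return np.array([self.truth.get(g, -1) for g in genes])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.write_mtx_dir(outdir)
        self.graph.write_edge_list(outdir / "graph_edges.tsv")
        pd.DataFrame(
            {"gene": list(self.truth), "module": list(self.truth.values())}
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _planted_graph(cfg: SimConfig, genes: list[str], module_of: np.ndarray, rng) -> GeneGraph:
    p = cfg.n_genes
    same = module_of[:, None] == module_of[None, :]
    in_module = (module_of >= 0)[:, None] & (module_of >= 0)[None, :] & same
    prob = np.where(in_module, cfg.p_in, cfg.p_out)
    iu = np.triu_indices(p, k=1)
    mask = rng.random(len(iu[0])) < prob[iu]
    A = sp.coo_matrix(
        (np.ones(mask.sum()), (iu[0][mask], iu[1][mask])), shape=(p, p)
    ).tocsr()
    A = A + A.T + sp.identity(p, format="csr")
    return GeneGraph(genes, A)


def generate(config: SimConfig) -> SyntheticDataset:
    """Draw one dataset under ``config``; byte-identical for equal seeds."""
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_graph, rng_act, rng_noise, rng_flip, rng_split = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    module_of = np.full(cfg.n_genes, -1)
    for m in range(cfg.n_modules):
        module_of[m * cfg.module_size : (m + 1) * cfg.module_size] = m
    truth = {genes[i]: int(module_of[i]) for i in np.flatnonzero(module_of >= 0)}

    graph = _planted_graph(cfg, genes, module_of, rng_graph)

    # donors and cell labels
    n_donors = 2 * cfg.n_donors_per_class
    donor_class = np.repeat([0, 1], cfg.n_donors_per_class)
    donor_ids = [f"D{i:03d}" for i in range(n_donors)]
    n_cells = n_donors * cfg.cells_per_donor
    cell_donor = np.repeat(np.arange(n_donors), cfg.cells_per_donor)
    cell_label = donor_class[cell_donor]

    # the class whose distribution each cell's activity is drawn from;
    # a cell_label_noise fraction per donor flips to the opposite class
    activity_class = cell_label.copy()
    for dref in range(n_donors):
        cells = np.flatnonzero(cell_donor == dref)
        n_flip = int(round(cfg.cell_label_noise * len(cells)))
        if n_flip:
            flip = rng_flip.choice(cells, size=n_flip, replace=False)
            activity_class[flip] = 1 - activity_class[flip]

    # module activities: Normal(class mean, 1); informative modules shift up
    mu = np.zeros((2, cfg.n_modules))
    for m in cfg.informative():
        mu[1, m] = cfg.effect_size
    acts = rng_act.normal(size=(n_cells, cfg.n_modules)) + mu[activity_class]

    # per-gene log intensity
    log_int = np.empty((n_cells, cfg.n_genes))
    in_mod = module_of >= 0
    log_int[:, in_mod] = acts[:, module_of[in_mod]]
    n_bg = int((~in_mod).sum())
    log_int[:, ~in_mod] = rng_act.normal(size=(n_cells, n_bg))
    log_int += rng_noise.normal(scale=cfg.noise_sd, size=log_int.shape)
    counts = rng_noise.poisson(_COUNT_SCALE * np.exp(log_int)).astype(np.int64)

    # donor-level train/test split, stratified by class
    split = np.empty(n_cells, dtype=object)
    donor_split = np.empty(n_donors, dtype=object)
    for cls in (0, 1):
        members = np.flatnonzero(donor_class == cls)
        n_train = int(round(cfg.train_donor_fraction * len(members)))
        shuffled = rng_split.permutation(members)
        donor_split[shuffled[:n_train]] = "train"
        donor_split[shuffled[n_train:]] = "test"
    split[:] = donor_split[cell_donor]

    obs = pd.DataFrame(
        {
            "donor_id": [donor_ids[i] for i in cell_donor],
            "label": cell_label,
            "split": split,
        },
        index=pd.Index([f"C{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    expr = ExpressionDataset(counts, genes, obs)
    return SyntheticDataset(expr, graph, truth)
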