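"""Synthetic two-sex, multi-replicate, multi-cell-type count data.

The generator draws each cell's type from its sex's proportion vector, then
draws per-gene counts from a negative binomial whose mean is a lognormal
library-size factor times a gene-by-type baseline, with an optional
within-type regulatory sex effect applied symmetrically (+lfc/2 to the
favored sex, -lfc/2 to the other, in log2 units) so the within-type log2
fold change equals the configured magnitude exactly.  Analytic ground truth
(mixture-mean bulk fold changes, abundance-driven and regulatory gene sets)
is returned alongside the counts.  Divergence tables are drawn per gene as
binomial substitution counts under group-specific omega.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import FEMALE, MALE, CellMetadata, CountMatrix

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid or inconsistent simulation configuration."""


@dataclasses.dataclass
class SimConfig:
    """Configuration for the count and divergence simulators."""

    n_genes: int = 200
    n_cell_types: int = 3
    n_replicates_per_sex: int = 3
    cells_per_sample: int = 8000
    type_proportions_female: Sequence[float] | None = None
    type_proportions_male: Sequence[float] | None = None
    baseline_means: np.ndarray | None = None  # genes x types; gamma-drawn if None
    baseline_shape: float = 2.0
    baseline_scale: float = 2.0
    nb_dispersion: float | Sequence[float] = 0.1  # variance = mu + phi mu^2
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.2
    dropout_rate: float = 0.0
    regulatory_fraction: float = 0.0
    regulatory_lfc: float = 2.0
    regulatory_assignments: Sequence[tuple[int, int, str]] | None = None
    omega_by_group: Mapping[str, float] | None = None
    lfc_threshold: float = 1.0  # threshold defining truth abundance-driven genes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.n_replicates_per_sex,
               self.cells_per_sample) < 1:
            raise ConfigurationError("all size parameters must be >= 1")
        for attr in ("type_proportions_female", "type_proportions_male"):
            p = getattr(self, attr)
            if p is None:
                p = np.full(self.n_cell_types, 1.0 / self.n_cell_types)
            p = np.asarray(p, dtype=float)
            if p.shape != (self.n_cell_types,):
                raise ConfigurationError(f"{attr} must have length n_cell_types")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{attr} must be nonnegative and sum to 1")
            setattr(self, attr, p)
        if self.baseline_means is not None:
            b = np.asarray(self.baseline_means, dtype=float)
            if b.shape != (self.n_genes, self.n_cell_types):
                raise ConfigurationError(
                    f"baseline_means shape {b.shape} != "
                    f"({self.n_genes}, {self.n_cell_types})"
                )
            if np.any(b < 0):
                raise ConfigurationError("baseline means must be nonnegative")
            self.baseline_means = b
        phi = np.broadcast_to(
            np.asarray(self.nb_dispersion, dtype=float), (self.n_genes,)
        ).copy()
        if np.any(phi < 0):
            raise ConfigurationError("dispersions must be >= 0")
        self._dispersion = phi
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.regulatory_fraction <= 1.0:
            raise ConfigurationError("regulatory_fraction must lie in [0, 1]")
        if self.regulatory_assignments is not None:
            for g, t, d in self.regulatory_assignments:
                if not (0 <= int(g) < self.n_genes and 0 <= int(t) < self.n_cell_types):
                    raise ConfigurationError(
                        f"regulatory assignment out of range: {(g, t, d)}"
                    )
                if d not in (FEMALE, MALE):
                    raise ConfigurationError(f"bad regulatory direction: {d!r}")

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"g{i:05d}" for i in range(self.n_genes)], dtype=object)

    @property
    def cell_type_labels(self) -> np.ndarray:
        return np.array([f"type{k}" for k in range(self.n_cell_types)], dtype=object)

    def to_flat_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            out[f.name] = v
        return out


@dataclasses.dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    regulatory_genes: set  # {(gene_id, cell_type_label, direction)}
    expected_bulk_lfc: np.ndarray  # per gene, log2(female mix mean / male mix mean)
    sex_limited: np.ndarray  # bool per gene: expressed in one sex's mixture only
    expected_abundance_driven: set  # gene ids
    group_label: np.ndarray  # per-gene divergence group

    def to_frame(self, gene_ids: np.ndarray) -> pd.DataFrame:
        reg_genes = {g for g, _, _ in self.regulatory_genes}
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "expected_bulk_lfc": self.expected_bulk_lfc,
                "sex_limited": self.sex_limited,
                "is_regulatory": [g in reg_genes for g in gene_ids],
                "is_abundance_driven": [
                    g in self.expected_abundance_driven for g in gene_ids
                ],
                "group_label": self.group_label,
            }
        )


# ---------------------------------------------------------------------------
# deterministic realization of the latent structure
# ---------------------------------------------------------------------------

def _realize(config: SimConfig):
    """Baseline means, regulatory assignments and per-sex effect factors.

    Drawn from a child stream of the seed so that ``simulate_counts`` and
    ``expected_bulk_lfc`` agree on the same realization.
    """
    rng = np.random.default_rng([config.seed, 0])
    if config.baseline_means is not None:
        baseline = config.baseline_means
    else:
        baseline = rng.gamma(
            config.baseline_shape, config.baseline_scale,
            size=(config.n_genes, config.n_cell_types),
        )
    if config.regulatory_assignments is not None:
        assignments = [
            (int(g), int(t), str(d)) for g, t, d in config.regulatory_assignments
        ]
        for g, t, d in assignments:
            if not (0 <= g < config.n_genes and 0 <= t < config.n_cell_types):
                raise ConfigurationError(f"regulatory assignment out of range: {(g, t, d)}")
            if d not in (FEMALE, MALE):
                raise ConfigurationError(f"bad regulatory direction: {d!r}")
    else:
        n_reg = int(np.floor(config.regulatory_fraction * config.n_genes))
        genes = rng.choice(config.n_genes, size=n_reg, replace=False)
        types = rng.integers(0, config.n_cell_types, size=n_reg)
        dirs = rng.choice([FEMALE, MALE], size=n_reg)
        assignments = [(int(g), int(t), str(d)) for g, t, d in zip(genes, types, dirs)]

    half = 2.0 ** (config.regulatory_lfc / 2.0)
    factor_f = np.ones((config.n_genes, config.n_cell_types))
    factor_m = np.ones((config.n_genes, config.n_cell_types))
    for g, t, d in assignments:
        if d == FEMALE:
            factor_f[g, t] *= half
            factor_m[g, t] /= half
        else:
            factor_f[g, t] /= half
            factor_m[g, t] *= half
    return baseline, assignments, factor_f, factor_m


def expected_bulk_lfc(config: SimConfig, return_sex_limited: bool = False):
    """Analytic per-gene log2 ratio of sex-specific mixture means.

    The mixture mean for a sex is sum_k pi_k * baseline[g, k] * effect[g, k];
    library-size scaling is common to both sexes and cancels.  Genes whose
    mixture mean is zero in exactly one sex get signed infinity and are
    flagged sex-limited; zero in both sexes gives NaN.
    """
    baseline, _, factor_f, factor_m = _realize(config)
    mix_f = (baseline * factor_f) @ config.type_proportions_female
    mix_m = (baseline * factor_m) @ config.type_proportions_male
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mix_f) - np.log2(mix_m)
    sex_limited = (mix_f > 0) ^ (mix_m > 0)
    lfc = np.where((mix_f == 0) & (mix_m == 0), np.nan, lfc)
    if return_sex_limited:
        return lfc, sex_limited
    return lfc


def _make_truth(config: SimConfig, assignments) -> SimTruth:
    gene_ids = config.gene_ids
    type_labels = config.cell_type_labels
    lfc, sex_limited = expected_bulk_lfc(config, return_sex_limited=True)
    reg_set = {(gene_ids[g], type_labels[t], d) for g, t, d in assignments}
    reg_genes = {g for g, _, _ in reg_set}
    finite = np.isfinite(lfc)
    driven = {
        gene_ids[i]
        for i in range(config.n_genes)
        if gene_ids[i] not in reg_genes
        and (
            (finite[i] and abs(lfc[i]) >= config.lfc_threshold) or sex_limited[i]
        )
    }
    groups = sorted(config.omega_by_group) if config.omega_by_group else ["all"]
    group_label = np.array(
        [groups[i % len(groups)] for i in range(config.n_genes)], dtype=object
    )
    return SimTruth(
        regulatory_genes=reg_set,
        expected_bulk_lfc=lfc,
        sex_limited=sex_limited,
        expected_abundance_driven=driven,
        group_label=group_label,
    )


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draw with variance mu + phi mu^2; phi = 0 rows fall back to Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    phi = np.broadcast_to(phi[:, None], mu.shape)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, CellMetadata, SimTruth]:
    """Simulate a full two-sex dataset; identical config => identical output."""
    baseline, assignments, factor_f, factor_m = _realize(config)
    rng = np.random.default_rng([config.seed, 1])
    phi = config._dispersion

    columns: list[sp.csr_matrix] = []
    meta_rows = []
    cell_ids = []
    for sex, props, factor in (
        (FEMALE, config.type_proportions_female, factor_f),
        (MALE, config.type_proportions_male, factor_m),
    ):
        mean_by_type = baseline * factor  # genes x types
        for rep in range(1, config.n_replicates_per_sex + 1):
            sample = f"{sex}_{rep}"
            n_cells = config.cells_per_sample
            types = rng.choice(config.n_cell_types, size=n_cells, p=props)
            lib = rng.lognormal(config.libsize_logmean, config.libsize_logsd, n_cells)
            mu = mean_by_type[:, types] * lib[None, :]
            block = _draw_nb(rng, mu, phi)
            if config.dropout_rate > 0:
                keep = rng.random(block.shape) >= config.dropout_rate
                block = block * keep
            columns.append(sp.csr_matrix(block))
            for j in range(n_cells):
                cid = f"{sample}_c{j:05d}"
                cell_ids.append(cid)
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "sample_id": sample,
                        "sex": sex,
                        "replicate": str(rep),
                        "cell_type": config.cell_type_labels[types[j]],
                    }
                )
    values = sp.hstack(columns, format="csr")
    counts = CountMatrix(values, config.gene_ids, np.asarray(cell_ids, dtype=object))
    meta = CellMetadata(pd.DataFrame(meta_rows))
    truth = _make_truth(config, assignments)
    return counts, meta, truth


def simulate_divergence(
    config: SimConfig,
    n_by_gene: Sequence[float] | float = 900,
    s_by_gene: Sequence[float] | float = 300,
    p_s: float = 0.1,
) -> pd.DataFrame:
    """Per-gene substitution counts under group-specific omega.

    DS ~ Binomial(S, p_s) and DN ~ Binomial(N, omega * p_s), with omega
    looked up from ``config.omega_by_group`` by the gene's group label.
    """
    omega_map = dict(config.omega_by_group or {"all": 0.2})
    for grp, omega in omega_map.items():
        if omega < 0:
            raise ConfigurationError(f"omega for group {grp!r} must be >= 0")
        if omega * p_s > 1:
            raise ConfigurationError(
                f"omega * p_s = {omega * p_s:g} > 1 for group {grp!r}"
            )
    if not 0 <= p_s <= 1:
        raise ConfigurationError("p_s must lie in [0, 1]")
    n_sites = np.broadcast_to(np.asarray(n_by_gene, float), (config.n_genes,))
    s_sites = np.broadcast_to(np.asarray(s_by_gene, float), (config.n_genes,))
    if np.any(n_sites <= 0) or np.any(s_sites <= 0):
        raise ConfigurationError("site counts must be positive")
    _, assignments, _, _ = _realize(config)
    truth = _make_truth(config, assignments)
    omega = np.array([omega_map[g] for g in truth.group_label])
    rng = np.random.default_rng([config.seed, 2])
    d_s = rng.binomial(s_sites.astype(int), p_s)
    d_n = rng.binomial(n_sites.astype(int), omega * p_s)
    return pd.DataFrame(
        {
            "gene_id": config.gene_ids,
            "group": truth.group_label,
            "DN": d_n,
            "DS": d_s,
            "N": n_sites.astype(int),
            "S": s_sites.astype(int),
            "dN": d_n / n_sites,
            "dS": d_s / s_sites,
        }
    )


def write_simulation(
    outdir: str,
    counts: CountMatrix,
    meta: CellMetadata,
    truth: SimTruth,
    config: SimConfig,
) -> None:
    """Write triplet counts, metadata TSV, truth TSV and a flat config file."""
    import os

    from .io_qc import write_counts

    os.makedirs(outdir, exist_ok=True)
    write_counts(counts, os.path.join(outdir, "counts"))
    meta.write_tsv(os.path.join(outdir, "metadata.tsv"))
    truth.to_frame(counts.gene_ids).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "sim_config.txt"), "w") as fh:
        for key, val in config.to_flat_dict().items():
            fh.write(f"{key}\t{val}\n")
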