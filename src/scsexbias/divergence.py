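"""Group-level coding-sequence divergence: aggregated dN, dS and dN/dS.

Per-gene inputs are substitution counts (DN, DS) and site counts (N, S); a
group's rates are total substitutions over total sites.  Uncertainty comes
from a percentile bootstrap over genes; group contrasts from label
permutation.  Genes with per-gene dS > 2 are excluded up front (saturation).
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "DN", "DS", "N", "S")
STATISTICS = ("dn", "ds", "omega")


def read_divergence(path: str) -> pd.DataFrame:
    """Read a per-gene divergence TSV (gene_id, DN, DS, N, S[, dN, dS])."""
    df = pd.read_csv(path, sep="\t")
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"divergence table missing column(s): {missing}")
    df = df.copy()
    for col in ("DN", "DS", "N", "S"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in column {col}")
    if (df["N"] <= 0).any() or (df["S"] <= 0).any():
        raise ValueError("site counts N and S must be positive")
    for col, num, den in (("dN", "DN", "N"), ("dS", "DS", "S")):
        expected = df[num] / df[den]
        if col in df.columns:
            if np.max(np.abs(df[col] - expected)) > 1e-9:
                raise ValueError(f"column {col} inconsistent with {num}/{den}")
        else:
            df[col] = expected
    return df


def filter_saturated(records: pd.DataFrame, ds_max: float = 2.0) -> pd.DataFrame:
    """Drop genes whose per-gene dS exceeds ``ds_max`` (strict inequality)."""
    records = validate_records(records)
    keep = records["dS"] <= ds_max
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("saturation filter removed %d gene(s) with dS > %g", n_removed, ds_max)
    return records[keep].reset_index(drop=True)


@dataclasses.dataclass
class GroupDivergence:
    """Aggregated divergence for one gene group."""

    group: str
    n_genes: int
    d_n: float
    d_s: float
    omega: float  # NaN when total DS is zero
    ci_dn: tuple[float, float] | None = None
    ci_ds: tuple[float, float] | None = None
    ci_omega: tuple[float, float] | None = None
    bootstrap_B: int = 0
    omega_undefined: bool = False


def _aggregate(dn_sub, n_sites, ds_sub, s_sites):
    d_n = dn_sub.sum() / n_sites.sum()
    tot_ds = ds_sub.sum()
    d_s = tot_ds / s_sites.sum()
    omega = d_n / d_s if tot_ds > 0 else np.nan
    return d_n, d_s, omega


def group_rates(records: pd.DataFrame, group: str = "all") -> GroupDivergence:
    """Point estimates: d_N = sum(DN)/sum(N), d_S = sum(DS)/sum(S), omega."""
    if len(records) == 0:
        raise ValueError("group_rates needs at least one gene")
    records = validate_records(records)
    d_n, d_s, omega = _aggregate(
        records["DN"].to_numpy(float),
        records["N"].to_numpy(float),
        records["DS"].to_numpy(float),
        records["S"].to_numpy(float),
    )
    return GroupDivergence(
        group=group,
        n_genes=len(records),
        d_n=float(d_n),
        d_s=float(d_s),
        omega=float(omega),
        omega_undefined=bool(np.isnan(omega)),
    )


def bootstrap_ci(
    records: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    group: str = "all",
) -> GroupDivergence:
    """Percentile bootstrap over genes for the aggregated rates.

    Replicates where the resampled total DS is zero are excluded from the
    omega interval (counted and warned).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    gd = group_rates(records, group=group)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dn = records["DN"].to_numpy(float)
    n = records["N"].to_numpy(float)
    ds = records["DS"].to_numpy(float)
    s = records["S"].to_numpy(float)
    m = len(records)
    idx = rng.integers(0, m, size=(B, m))
    sum_dn = dn[idx].sum(axis=1)
    sum_n = n[idx].sum(axis=1)
    sum_ds = ds[idx].sum(axis=1)
    sum_s = s[idx].sum(axis=1)
    rep_dn = sum_dn / sum_n
    rep_ds = sum_ds / sum_s
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    gd.ci_dn = tuple(np.percentile(rep_dn, [lo, hi]))
    gd.ci_ds = tuple(np.percentile(rep_ds, [lo, hi]))
    ok = sum_ds > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "group %s: %d/%d bootstrap replicate(s) had zero total DS; "
            "excluded from the omega interval",
            group, n_bad, B,
        )
    if ok.any():
        rep_omega = sum_dn[ok] / sum_n[ok] / (sum_ds[ok] / sum_s[ok])
        gd.ci_omega = tuple(np.percentile(rep_omega, [lo, hi]))
    gd.bootstrap_B = B
    return gd


def permutation_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    B: int = 1000,
    statistic: str = "omega",
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for the difference in an aggregated statistic.

    Genes are pooled, labels shuffled preserving group sizes; p = (1 + number
    of permuted |differences| >= |observed|) / (B + 1).  ``alternative`` may
    be 'two-sided', 'greater' (a > b) or 'less'.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    a = validate_records(records_a)
    b = validate_records(records_b)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cols = ("DN", "N", "DS", "S")
    pooled = {c: np.concatenate([a[c].to_numpy(float), b[c].to_numpy(float)]) for c in cols}
    n_a, n_tot = len(a), len(a) + len(b)

    def stat_diff(idx_a, idx_b):
        vals = []
        for idx in (idx_a, idx_b):
            d_n, d_s, omega = _aggregate(
                pooled["DN"][idx], pooled["N"][idx], pooled["DS"][idx], pooled["S"][idx]
            )
            vals.append({"dn": d_n, "ds": d_s, "omega": omega}[statistic])
        return vals[0] - vals[1]

    obs = stat_diff(np.arange(n_a), np.arange(n_a, n_tot))
    if np.isnan(obs):
        raise ValueError("observed statistic undefined (zero total DS in a group)")

    # vectorized permutations: each row of `perm` is a shuffled gene order
    keys = rng.random((B, n_tot))
    perm = np.argsort(keys, axis=1)
    idx_a = perm[:, :n_a]
    idx_b = perm[:, n_a:]

    def agg(idx):
        sum_dn = pooled["DN"][idx].sum(axis=1)
        sum_n = pooled["N"][idx].sum(axis=1)
        sum_ds = pooled["DS"][idx].sum(axis=1)
        sum_s = pooled["S"][idx].sum(axis=1)
        d_n = sum_dn / sum_n
        d_s = sum_ds / sum_s
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = np.where(sum_ds > 0, d_n / np.where(d_s > 0, d_s, np.nan), np.nan)
        return {"dn": d_n, "ds": d_s, "omega": omega}[statistic]

    diffs = agg(idx_a) - agg(idx_b)
    ok = ~np.isnan(diffs)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d/%d permutation replicate(s) undefined; excluded", n_bad, B)
    diffs = diffs[ok]
    b_eff = diffs.size
    if alternative == "two-sided":
        n_extreme = int((np.abs(diffs) >= abs(obs)).sum())
    elif alternative == "greater":
        n_extreme = int((diffs >= obs).sum())
    else:
        n_extreme = int((diffs <= obs).sum())
    return (1 + n_extreme) / (b_eff + 1)


# ---------------------------------------------------------------------------
# Category comparison / compact letter display
# ---------------------------------------------------------------------------

def compact_letters(names: list, sig_pairs: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    Groups in ``sig_pairs`` (significantly different) never share a letter;
    any pair not listed shares at least one letter.
    """
    sets: list[set] = [set(names)]
    for i, j in sig_pairs:
        new_sets = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s
            for k, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and k > l) for l, t in enumerate(new_sets))
        ]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(letters, sets):
        for name in s:
            out[name] += letter
    return {k: "".join(sorted(v)) for k, v in out.items()}


def compare_categories(
    categories: pd.DataFrame,
    records: pd.DataFrame,
    bootstrap_B: int = 1000,
    perm_B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ds_max: float = 2.0,
    statistic: str = "omega",
) -> pd.DataFrame:
    """Per-category aggregated divergence with CIs and pairwise letters.

    Groups follow the bulk/cell decomposition layout: unbiased; bulk-level
    (male/female); bulk-only, bulk-and-cell and cell-only, each split by
    direction.  Empty groups are skipped with a notice.
    """
    records = filter_saturated(records, ds_max=ds_max)
    merged = categories.merge(records, on="gene_id", how="inner")
    rng = np.random.default_rng(seed)

    groups: dict[str, pd.DataFrame] = {}

    def add(name, frame):
        if len(frame):
            groups[name] = frame
        else:
            logger.info("category %s is empty; skipped", name)

    add("unbiased", merged[merged["category"] == "unbiased"])
    for direction in ("female", "male"):
        d = merged[merged["direction"] == direction]
        add(f"bulk_level_{direction}", d[d["category"].isin(["bulk_only", "bulk_and_cell"])])
        for cat in ("bulk_only", "bulk_and_cell", "cell_only"):
            add(f"{cat}_{direction}", d[d["category"] == cat])

    results = {
        name: bootstrap_ci(frame, B=bootstrap_B, seed=rng, group=name)
        for name, frame in groups.items()
    }

    names = list(groups)
    sig_pairs = set()
    pair_p = {}
    for a, b in combinations(names, 2):
        p = permutation_test(groups[a], groups[b], B=perm_B, statistic=statistic, seed=rng)
        pair_p[(a, b)] = p
        if p < alpha:
            sig_pairs.add((a, b))
    letters = compact_letters(names, sig_pairs) if len(names) > 1 else {n: "a" for n in names}

    rows = []
    for name in names:
        gd = results[name]
        rows.append(
            {
                "group": name,
                "n_genes": gd.n_genes,
                "d_n": gd.d_n,
                "d_s": gd.d_s,
                "omega": gd.omega,
                "ci_dn_low": gd.ci_dn[0],
                "ci_dn_high": gd.ci_dn[1],
                "ci_ds_low": gd.ci_ds[0],
                "ci_ds_high": gd.ci_ds[1],
                "ci_omega_low": gd.ci_omega[0] if gd.ci_omega else np.nan,
                "ci_omega_high": gd.ci_omega[1] if gd.ci_omega else np.nan,
                "letters": letters[name],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["pairwise_p"] = {f"{a}|{b}": p for (a, b), p in pair_p.items()}
    return out
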