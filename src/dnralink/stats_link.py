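"""Linking DNRA community structure to activity.

Joins per-site summaries (tracer-derived DNRA rates, nrfA gene copies,
diversity indices, dominant/endemic percentages) with site geochemistry and
tests the relationships: Pearson correlations with two-tailed t-based
p-values, one-way ANOVA, and canonical correspondence analysis (CCA) of the
dominant-OTU table against environmental variables.  The packaged site
tables (data/table*.tsv) carry the printed five-site study values so the
headline statistics can be recomputed from the tables alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "CCAResult",
    "pearson",
    "anova_oneway",
    "cca",
    "load_study_tables",
    "site_summaries",
    "build_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Product-moment correlation; p two-tailed from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return CorrelationResult(x_name, y_name, float("nan"), float("nan"), n)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), n)


def anova_oneway(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F and p."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


@dataclass
class CCAResult:
    eigenvalues: np.ndarray  # constrained eigenvalues, descending
    site_scores: pd.DataFrame  # linear-combination site scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # env variable loadings on the axes
    total_inertia: float
    constrained_inertia: float

    @property
    def proportion_explained(self) -> np.ndarray:
        """Share of constrained inertia per axis."""
        return self.eigenvalues / self.eigenvalues.sum()

    def cumulative_percent(self, k: int = 2) -> float:
        """Percent of constrained variance carried by the first k axes."""
        return 100.0 * float(self.proportion_explained[:k].sum())


def cca(species: pd.DataFrame, env: pd.DataFrame) -> CCAResult:
    """Canonical correspondence analysis (ter Braak).

    ``species``: site x OTU non-negative counts; ``env``: site x variable.
    With n sites at most n - 2 environmental variables are accepted —
    beyond that the ordination is over-parameterized and the call refuses,
    naming the limit (choose a subset, e.g. by forward selection on
    constrained-inertia gain).
    """
    if species.shape[0] != env.shape[0]:
        raise ValueError("species and env must describe the same sites")
    n_sites, n_vars = env.shape
    if n_sites < n_vars + 2:
        raise ValueError(
            f"{n_sites} sites support at most {n_sites - 2} environmental "
            f"variables; got {n_vars} — select a subset"
        )
    y = species.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("species counts must be non-negative")
    if (y.sum(axis=1) <= 0).any() or (y.sum(axis=0) <= 0).any():
        raise ValueError("species rows and columns must have positive sums")
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)  # site weights
    c = p.sum(axis=0)  # species weights
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))  # chi-square standardized
    x = env.to_numpy(dtype=float)
    xc = x - np.average(x, axis=0, weights=r)  # weighted centering
    xw = xc * np.sqrt(r)[:, None]
    # weighted least-squares projection of q onto the env space
    beta, *_ = np.linalg.lstsq(xw, q, rcond=None)
    fitted = xw @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = min(n_vars, species.shape[1] - 1, n_sites - 1)
    keep = np.flatnonzero(s[:rank] ** 2 > 1e-12)
    s = s[keep]
    u = u[:, keep]
    vt = vt[keep]
    eig = s**2
    axes = [f"CCA{k + 1}" for k in range(eig.size)]
    site_scores = pd.DataFrame(
        (u / np.sqrt(r)[:, None]) * s, index=species.index, columns=axes
    )
    species_scores = pd.DataFrame(
        vt.T / np.sqrt(c)[:, None], index=species.columns, columns=axes
    )
    biplot = np.array(
        [
            [np.corrcoef(xw[:, vi], u[:, ax])[0, 1] for ax in range(eig.size)]
            for vi in range(n_vars)
        ]
    )
    biplot_scores = pd.DataFrame(biplot, index=env.columns, columns=axes)
    return CCAResult(
        eigenvalues=eig,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
        total_inertia=float((q**2).sum()),
        constrained_inertia=float(eig.sum()),
    )


# ---------------------------------------------------------------------------
# study tables and report
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "geochem": "table1_geochem.tsv",
    "rates": "table2_rates.tsv",
    "filtering": "table3_filtering.tsv",
    "diversity": "table4_diversity.tsv",
}


def load_study_tables(directory: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Load the packaged five-site study tables (or same-named files in a dir)."""
    tables = {}
    for key, fname in _TABLE_FILES.items():
        if directory is None:
            ref = resources.files("dnralink.data").joinpath(fname)
            with resources.as_file(ref) as path:
                tables[key] = pd.read_csv(path, sep="\t")
        else:
            tables[key] = pd.read_csv(Path(directory) / fname, sep="\t")
    return tables


def site_summaries(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join the per-site tables into one summary frame keyed by site_id."""
    merged = (
        tables["rates"]
        .merge(tables["filtering"], on="site_id")
        .merge(tables["diversity"], on="site_id")
        .merge(tables["geochem"], on="site_id")
        .sort_values("site_id", ignore_index=True)
    )
    out = pd.DataFrame(
        {
            "site_id": merged.site_id,
            "dnra_rate": merged.dnra_rate_nmol_n_g_h,
            "nrfa_copies_per_g": merged.nrfa_copies_per_g,
            "shannon_H": merged.shannon_h,
            "S_obs": merged.otus,
            "evenness": merged.evenness_j,
            "pct_dominant": merged.pct_dominant,
            "pct_endemic": merged.pct_endemic,
        }
    )
    bad = (out.pct_dominant < 0) | (out.pct_dominant > 100)
    if bad.any() or ((out.pct_endemic < 0) | (out.pct_endemic > 100)).any():
        raise ValueError("percentages must lie in [0, 100]")
    return out


#: the printed headline relationships, checked at printed precision
_HEADLINE_CORRELATIONS = [
    ("extractable_nh4_umol_g", "shannon_h", -0.94),
    ("pct_dominant", "dnra_rate_nmol_n_g_h", 0.92),
    ("pct_dominant", "nrfa_copies_per_g", 0.99),
    ("pct_endemic", "dnra_rate_nmol_n_g_h", -0.93),
]

_HEADLINE_EVENNESS = {"AA2": 0.940, "M31": 0.920, "M15": 0.943}


def build_report(tables: dict[str, pd.DataFrame]) -> dict:
    """Per-site summary, all-pairs correlation matrix and headline checks.

    The headline checks recompute the four printed correlations (to two
    decimals) and three evenness values (to three decimals) from the site
    tables alone.
    """
    summary = site_summaries(tables)
    merged = (
        tables["rates"]
        .merge(tables["filtering"], on="site_id")
        .merge(tables["diversity"], on="site_id")
        .merge(tables["geochem"], on="site_id")
        .sort_values("site_id", ignore_index=True)
    )
    structural = [
        "dnra_rate_nmol_n_g_h",
        "nrfa_copies_per_g",
        "shannon_h",
        "evenness_j",
        "pct_dominant",
        "pct_endemic",
    ]
    environmental = [
        "salinity_ppt",
        "bw_no3_uM",
        "bw_nh4_uM",
        "pct_organic",
        "h2s_uM",
        "nox_uM",
        "extractable_nh4_umol_g",
    ]
    rows = []
    for a in structural:
        for b in structural + environmental:
            if a == b:
                continue
            res = pearson(merged[a], merged[b], a, b)
            rows.append(
                {"x": a, "y": b, "r": round(res.r, 2), "p": round(res.p, 4), "n": res.n}
            )
    correlations = pd.DataFrame(rows)

    checks = []
    for a, b, printed in _HEADLINE_CORRELATIONS:
        res = pearson(merged[a], merged[b], a, b)
        checks.append(
            {
                "check": f"r({a}, {b})",
                "computed": round(res.r, 2),
                "printed": printed,
                "pass": round(res.r, 2) == printed,
            }
        )
    div = tables["diversity"].set_index("site_id")
    for site, printed in _HEADLINE_EVENNESS.items():
        j = div.loc[site, "shannon_h"] / np.log(div.loc[site, "otus"])
        checks.append(
            {
                "check": f"evenness({site})",
                "computed": round(float(j), 3),
                "printed": printed,
                "pass": round(float(j), 3) == printed,
            }
        )
    return {
        "summary": summary,
        "correlations": correlations,
        "headline_checks": pd.DataFrame(checks),
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["summary"].to_csv(out / "site_summary.tsv", sep="\t", index=False)
    report["correlations"].to_csv(out / "correlations.tsv", sep="\t", index=False)
    report["headline_checks"].to_csv(out / "headline_checks.tsv", sep="\t", index=False)
    lines = ["# DNRA structure-activity report", ""]
    for row in report["headline_checks"].itertuples():
        status = "ok" if row._4 else "MISMATCH"
        lines.append(f"- {row.check}: computed {row.computed} vs printed {row.printed} [{status}]")
    (out / "report.md").write_text("\n".join(lines) + "\n")
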