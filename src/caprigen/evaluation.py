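"""Reference/validation design, accuracy, the factorial grid, ANOVA + Duncan.

The study design is one-factor-at-a-time: marker density, QTL number and
reference size are varied one at a time around a per-trait baseline cell,
every cell is simulated in replicate, and all prediction methods are fitted
on the same replicate.  Accuracy is the Pearson correlation between the
predicted values (GEBV) and the realised values of the validation animals.
The realised vector defaults to true breeding values; simulated phenotypes
are available as an option (see the methods note on why TBV is the default).

Reporting mirrors classical fixed-effects GLM output: sequential (Type I)
sums of squares over the listed factors, and Duncan's multiple range test
for letter-grouped level means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from . import prediction
from .population import RecentResult

__all__ = [
    "ExperimentDesign",
    "Scenario",
    "split_reference_validation",
    "make_scenario",
    "compute_accuracy",
    "fit_method",
    "run_factorial",
    "anova_glm",
    "duncan_mrt",
    "format_anova",
    "format_duncan",
]

ALL_METHODS = ("BayesA", "BayesB", "BL", "BRR", "GBLUP", "ssGBLUP")


@dataclass
class ExperimentDesign:
    """Factor levels for the accuracy study.

    The default levels are the full-scale study; profiles may shrink them.
    ``baseline`` holds the cell shared across the one-factor comparisons.
    """

    marker_densities: tuple = (15000, 30000, 45000, 60000)
    qtl_numbers: tuple = (50, 100, 150)
    ref_sizes: tuple = (500, 1000, 1500, 2000, 3000)
    methods: tuple = ALL_METHODS
    sex_compositions: tuple = (
        (100, 1400), (200, 1300), (400, 1100), (800, 700), (1200, 300), (1500, 0),
    )
    replicates: int = 3
    val_size: int = 1000
    baseline: dict = field(default_factory=lambda: {
        "marker_density": 45000, "n_qtl": 100, "ref_size": 1500})

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def baseline_fd(cls, **kw) -> "ExperimentDesign":
        """Fiber-diameter baseline: 60 K markers, 1,500 reference, 150 QTLs."""
        return cls(baseline={"marker_density": 60000, "n_qtl": 150,
                             "ref_size": 1500}, **kw)

    @classmethod
    def baseline_lbw(cls, **kw) -> "ExperimentDesign":
        """Live-body-weight baseline: 45 K markers, 3,000 reference, 100 QTLs."""
        return cls(baseline={"marker_density": 45000, "n_qtl": 100,
                             "ref_size": 3000}, **kw)

    def main_cells(self) -> list[dict]:
        """One scenario cell per factor level (other factors at baseline)."""
        cells = []
        for d in self.marker_densities:
            cells.append({**self.baseline, "marker_density": d, "factor": "marker_density"})
        for q in self.qtl_numbers:
            cells.append({**self.baseline, "n_qtl": q, "factor": "n_qtl"})
        for r in self.ref_sizes:
            cells.append({**self.baseline, "ref_size": r, "factor": "ref_size"})
        return cells

    def main_table(self) -> pd.DataFrame:
        """Full record index of the main study (cells x methods x replicates)."""
        rows = []
        for cell in self.main_cells():
            for method in self.methods:
                for rep in range(self.replicates):
                    rows.append({**cell, "method": method, "replicate": rep})
        return pd.DataFrame(rows)

    def sex_table(self) -> pd.DataFrame:
        """Record index of the male-composition study at the baseline cell."""
        rows = []
        for males, females in self.sex_compositions:
            label = f"{males}M+{females}F"
            for method in self.methods:
                for rep in range(self.replicates):
                    rows.append({**self.baseline, "factor": "sex_composition",
                                 "sex_composition": label, "males": males,
                                 "females": females, "method": method,
                                 "replicate": rep})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference / validation split
# ---------------------------------------------------------------------------

def split_reference_validation(
    records: pd.DataFrame,
    ref_size: int,
    val_size: int,
    rng: np.random.Generator,
    sex_composition: tuple[int, int] | None = None,
    ref_generations: tuple[int, int] = (2, 7),
    val_generations: tuple[int, int] = (8, 10),
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint reference/validation id sets from generation windows.

    Reference animals come from generations 2–7, validation animals from
    8–10.  ``sex_composition`` = (males, females) forces exact reference sex
    counts (and must sum to ``ref_size``).
    """
    gen = records["generation"].to_numpy()
    ref_pool = records.loc[(gen >= ref_generations[0]) & (gen <= ref_generations[1])]
    val_pool = records.loc[(gen >= val_generations[0]) & (gen <= val_generations[1])]
    if sex_composition is None:
        if len(ref_pool) < ref_size:
            raise ValueError("not enough reference candidates")
        ref = rng.choice(ref_pool["id"].to_numpy(), size=ref_size, replace=False)
    else:
        n_m, n_f = sex_composition
        if n_m + n_f != ref_size:
            raise ValueError("sex composition must sum to the reference size")
        males = ref_pool.loc[ref_pool["sex"] == "M", "id"].to_numpy()
        females = ref_pool.loc[ref_pool["sex"] == "F", "id"].to_numpy()
        if males.size < n_m or females.size < n_f:
            raise ValueError("infeasible sex composition for the reference pool")
        ref = np.concatenate([
            rng.choice(males, size=n_m, replace=False),
            rng.choice(females, size=n_f, replace=False),
        ])
    if len(val_pool) < val_size:
        raise ValueError("not enough validation candidates")
    val = rng.choice(val_pool["id"].to_numpy(), size=val_size, replace=False)
    return np.sort(ref), np.sort(val)


@dataclass
class Scenario:
    """Inputs one prediction method needs for one replicate."""

    genotypes: pd.DataFrame      # id-indexed marker allele counts (ref + val)
    phenotypes: pd.Series        # id-indexed, every recorded animal
    tbv: pd.Series
    pedigree: pd.DataFrame
    ref_ids: np.ndarray
    val_ids: np.ndarray
    h2: float


def make_scenario(
    recent: RecentResult,
    ref_size: int,
    val_size: int,
    rng: np.random.Generator,
    sex_composition: tuple[int, int] | None = None,
) -> Scenario:
    """Split a simulated recent population into a prediction scenario."""
    ref, val = split_reference_validation(
        recent.records, ref_size, val_size, rng, sex_composition)
    ids = recent.population.ids
    pos = pd.Index(ids)
    sel = pos.get_indexer(np.concatenate([ref, val]))
    counts = recent.population.genotypes(recent.gmap.marker_index)[sel]
    genotypes = pd.DataFrame(counts, index=pd.Index(np.concatenate([ref, val]), name="id"))
    rec = recent.records.set_index("id")
    return Scenario(
        genotypes=genotypes,
        phenotypes=rec["phenotype"],
        tbv=rec["tbv"],
        pedigree=recent.pedigree,
        ref_ids=ref,
        val_ids=val,
        h2=recent.trait.h2,
    )


def compute_accuracy(predicted, realized) -> float:
    """Pearson correlation between predicted and realised values."""
    predicted = np.asarray(predicted, dtype=float)
    realized = np.asarray(realized, dtype=float)
    if predicted.shape != realized.shape or predicted.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.var(predicted) == 0 or np.var(realized) == 0:
        raise ValueError("accuracy undefined for a constant vector")
    return float(stats.pearsonr(predicted, realized).statistic)


def fit_method(
    method: str,
    scenario: Scenario,
    seed: int = 0,
    chain_kwargs: dict | None = None,
) -> pd.Series:
    """Fit one prediction method and return GEBV for the validation ids."""
    yref = scenario.phenotypes.loc[scenario.ref_ids]
    if method == "GBLUP":
        res = prediction.gblup(yref, scenario.genotypes, scenario.h2)
    elif method == "ssGBLUP":
        masked = scenario.phenotypes.copy()
        masked.loc[scenario.val_ids] = np.nan
        res = prediction.ssgblup(masked, scenario.pedigree,
                                 scenario.genotypes, scenario.h2)
    elif method in prediction.BAYES_METHODS:
        kw = dict(chain_kwargs or {})
        kw.setdefault("h2", scenario.h2)
        post = prediction.bayes_gibbs(method, yref, scenario.genotypes,
                                      rng_seed=seed, **kw)
        res = prediction.predict_gebv(post, scenario.genotypes)
    else:
        raise ValueError(f"unknown method {method!r}")
    return res.gebv.loc[scenario.val_ids]


def run_factorial(
    design: ExperimentDesign,
    scenario_fn,
    seed: int = 0,
    realized: str = "tbv",
    chain_kwargs: dict | None = None,
    include_sex_study: bool = False,
) -> pd.DataFrame:
    """Run the one-factor-at-a-time grid: one accuracy record per
    (scenario level x method x replicate).

    ``scenario_fn(cell: dict, replicate: int, rng) -> Scenario`` owns the
    simulation; all methods are fitted on the same replicate scenario.
    """
    if realized not in ("tbv", "phenotype"):
        raise ValueError("realized must be 'tbv' or 'phenotype'")
    cells = design.main_cells()
    if include_sex_study:
        for males, females in design.sex_compositions:
            cells.append({**design.baseline, "factor": "sex_composition",
                          "sex_composition": (males, females)})
    ss = np.random.SeedSequence(seed)
    records = []
    for cell in cells:
        for rep in range(design.replicates):
            rng = np.random.default_rng(ss.spawn(1)[0])
            sc = scenario_fn(cell, rep, rng)
            real = (sc.tbv if realized == "tbv" else sc.phenotypes).loc[sc.val_ids]
            for method in design.methods:
                gebv = fit_method(method, sc, seed=int(rng.integers(2**31 - 1)),
                                  chain_kwargs=chain_kwargs)
                comp = cell.get("sex_composition")
                records.append({
                    "factor": cell["factor"],
                    "marker_density": cell["marker_density"],
                    "n_qtl": cell["n_qtl"],
                    "ref_size": cell["ref_size"],
                    "sex_composition": (f"{comp[0]}M+{comp[1]}F" if comp else ""),
                    "method": method,
                    "replicate": rep,
                    "r": compute_accuracy(gebv, real),
                })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# GLM (sequential ANOVA) and Duncan's multiple range test
# ---------------------------------------------------------------------------

def anova_glm(records: pd.DataFrame, factors: list[str],
              response: str = "r") -> pd.DataFrame:
    """Additive fixed-effects ANOVA with sequential (Type I) sums of squares.

    Returns a table with Source, DF, SS, MS, F, P rows for every factor in
    the listed order, plus Error and Corrected Total rows.
    """
    for f in factors:
        if records[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=records).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    tab = anova_lm(fit, typ=1)
    rows = []
    for f in factors:
        row = tab.loc[f"C({f})"]
        rows.append({"Source": f, "DF": int(row["df"]), "SS": row["sum_sq"],
                     "MS": row["sum_sq"] / row["df"], "F": row["F"],
                     "P": row["PR(>F)"]})
    resid = tab.loc["Residual"]
    rows.append({"Source": "Error", "DF": int(resid["df"]),
                 "SS": resid["sum_sq"], "MS": resid["sum_sq"] / resid["df"],
                 "F": np.nan, "P": np.nan})
    y = records[response].to_numpy(dtype=float)
    rows.append({"Source": "Corrected Total", "DF": y.size - 1,
                 "SS": float(np.sum((y - y.mean()) ** 2)),
                 "MS": np.nan, "F": np.nan, "P": np.nan})
    return pd.DataFrame(rows)


def duncan_mrt(
    means: pd.Series,
    counts: pd.Series,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan's multiple range test with letter groupings.

    Levels are sorted by mean (descending).  The critical range for a span
    of ``p`` ordered means uses the protected level
    ``alpha_p = 1 - (1 - alpha)**(p - 1)`` and the studentized-range
    quantile q(1 - alpha_p; p, df) * sqrt(MS_error / n_h), with n_h the
    harmonic mean of the level counts in the span.  A non-significant range
    declares every level inside it homogeneous (no further testing), and
    maximal homogeneous runs share a letter.
    """
    if df_error <= 0:
        raise ValueError("error degrees of freedom must be positive")
    if len(means) < 2:
        raise ValueError("need at least two levels")
    order = means.sort_values(ascending=False)
    m = order.to_numpy(dtype=float)
    n = counts.loc[order.index].to_numpy(dtype=float)
    k = m.size
    homog = np.eye(k, dtype=bool)
    for p in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        for i in range(0, k - p + 1):
            j = i + p - 1
            if homog[i, j]:
                continue
            nh = p / np.sum(1.0 / n[i : j + 1])
            crit = stats.studentized_range.ppf(1.0 - alpha_p, p, df_error)
            crit *= np.sqrt(ms_error / nh)
            if m[i] - m[j] < crit:
                homog[i : j + 1, i : j + 1] = True
    # maximal homogeneous runs -> letters
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and homog[i, j + 1]:
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    letters = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for r, (i, j) in enumerate(runs):
        for t in range(i, j + 1):
            letters[t] += alphabet[r % len(alphabet)]
    return pd.DataFrame({"level": order.index, "mean": m, "n": n.astype(int),
                         "letters": letters})


def format_anova(table: pd.DataFrame, title: str = "") -> str:
    """Aligned text rendering of an ANOVA table."""
    lines = [title] if title else []
    lines.append(f"{'Source':<28}{'DF':>5}{'SS':>12}{'MS':>12}{'F':>10}{'P':>12}")
    for _, row in table.iterrows():
        f = "" if pd.isna(row["F"]) else f"{row['F']:.2f}"
        p = "" if pd.isna(row["P"]) else f"{row['P']:.4g}"
        ms = "" if pd.isna(row["MS"]) else f"{row['MS']:.4f}"
        lines.append(f"{row['Source']:<28}{int(row['DF']):>5}{row['SS']:>12.4f}"
                     f"{ms:>12}{f:>10}{p:>12}")
    return "\n".join(lines)


def format_duncan(table: pd.DataFrame, title: str = "") -> str:
    lines = [title] if title else []
    lines.append(f"{'Level':<20}{'Mean':>10}{'n':>6}  Group")
    for _, row in table.iterrows():
        lines.append(f"{str(row['level']):<20}{row['mean']:>10.4f}"
                     f"{int(row['n']):>6}  {row['letters']}")
    return "\n".join(lines)
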