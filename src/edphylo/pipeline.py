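"""End-to-end orchestration of the comparative analysis.

Stages: load the species trait table -> allometric EDP residuals -> design
matrix (intercept + clutch size + foraging + activity + nest, with a
missing-data policy) -> reconcile table and tree -> Brownian covariance ->
lambda-ML PGLS -> report (coefficient table, lambda, r^2, provenance).

The packaged trait table reproduces the 33 auk and penguin species of the
study this pipeline reimplements: EDP in days, fresh egg mass in grams,
clutch size (1/2), foraging habitat (0 = inshore, 1 = offshore), activity
pattern (0 = nocturnal/crepuscular, 1 = diurnal) and nest type (0 = enclosed,
1 = open).  Two penguins (erect-crested and yellow-eyed) have no recorded
foraging habitat.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from . import allometry
from .allometry import AllometricParams, ResidualRecord
from .pgls import (
    DesignMatrix,
    PglsFit,
    PglsOptions,
    coefficient_tests,
    fit_pgls,
)
from .trees import (
    PhyloTree,
    TreeSample,
    discard_burnin,
    majority_rule_consensus,
    parse_newick,
    prune,
    read_tree_sample,
    root_on_outgroup,
    vcv_matrix,
)

__all__ = [
    "TraitTable",
    "AnalysisOptions",
    "AnalysisReport",
    "load_trait_table",
    "load_paper_table",
    "load_standin_tree",
    "reconcile",
    "build_design_matrix",
    "run_paper_analysis",
    "consensus_workflow",
    "plot_edp_allometry",
]

logger = logging.getLogger("edphylo")

PREDICTORS = ("clutch_size", "foraging", "activity", "nest")
REQUIRED_COLUMNS = ("species", "edp_days", "egg_mass_g") + PREDICTORS
OPTIONAL_COLUMNS = ("common_name", "accession", "edpr_printed")


class TraitTableError(ValueError):
    """The trait table violates the schema; message lists every bad row."""


@dataclass
class TraitTable:
    """Validated species trait records (one row per species).

    Missing predictor values (``-`` or empty in the file) are NaN in ``df``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        problems: list[str] = []
        cols = set(self.df.columns)
        for c in REQUIRED_COLUMNS:
            if c not in cols:
                problems.append(f"missing required column {c!r}")
        unknown = cols - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
        if unknown:
            problems.append(f"unknown columns {sorted(unknown)}")
        if problems:
            raise TraitTableError("; ".join(problems))
        df = self.df
        dup = df["species"][df["species"].duplicated()].tolist()
        if dup:
            problems.append(f"duplicate species {sorted(set(dup))}")
        for i, row in df.iterrows():
            cs = row["clutch_size"]
            if not (pd.isna(cs) or cs in (1, 2)):
                problems.append(
                    f"row {i} ({row['species']}): clutch_size {cs!r} not in {{1,2}}"
                )
            for c in ("foraging", "activity", "nest"):
                v = row[c]
                if not (pd.isna(v) or v in (0, 1)):
                    problems.append(
                        f"row {i} ({row['species']}): {c} {v!r} not in {{0,1}}"
                    )
        if problems:
            raise TraitTableError(
                "invalid trait table:\n  " + "\n  ".join(problems)
            )

    @property
    def species(self) -> list[str]:
        return self.df["species"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def restrict(self, species: Iterable[str]) -> "TraitTable":
        keep = list(species)
        sub = self.df[self.df["species"].isin(keep)].copy()
        sub["__order"] = sub["species"].map({s: i for i, s in enumerate(keep)})
        sub = sub.sort_values("__order").drop(columns="__order")
        return TraitTable(sub.reset_index(drop=True))


def load_trait_table(path: str) -> TraitTable:
    """Read a delimited (comma or tab) trait table.

    A header row is required; ``-`` and empty cells are read as missing.
    """
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        na_values=["-", ""],
        skipinitialspace=True,
    )
    df["species"] = df["species"].astype(str)
    table = TraitTable(df)
    if len(table) == 0:
        logger.warning("trait table %s contains a header but no records", path)
    return table


def load_paper_table() -> TraitTable:
    """The packaged 33-species auk + penguin trait table."""
    with resources.as_file(
        resources.files("edphylo").joinpath("data/table1.csv")
    ) as p:
        return load_trait_table(str(p))


def load_standin_tree() -> PhyloTree:
    """SYNTHETIC stand-in consensus tree for the 33 study species.

    The topology follows the accepted genus-level phylogeny of auks and
    penguins (genera monophyletic, the two families reciprocally
    monophyletic); it is NOT the study's own consensus tree, whose branch
    lengths were never published.  Branch lengths are assigned by the
    node-depth rule (every internal node one unit above its highest child),
    giving an ultrametric tree in arbitrary units.  Suitable for exercising
    the pipeline; not for reproducing headline estimates exactly.
    """
    text = (
        resources.files("edphylo")
        .joinpath("data/synthetic_consensus_tree.nwk")
        .read_text(encoding="utf-8")
    )
    tree = parse_newick(text)
    _ultrametricize_node_depth(tree)
    return tree


def _ultrametricize_node_depth(tree: PhyloTree) -> None:
    """Assign branch lengths so each node sits one unit above its tallest
    child; tips end up contemporaneous (height 0)."""

    def height(n) -> int:
        if n.is_leaf:
            return 0
        return 1 + max(height(c) for c in n.children)

    def assign(n, h: int) -> None:
        for c in n.children:
            hc = height(c)
            c.length = float(h - hc)
            assign(c, hc)

    assign(tree.root, height(tree.root))


# ---------------------------------------------------------------------------
# Reconciliation and design
# ---------------------------------------------------------------------------


def reconcile(
    traits: TraitTable, tree: PhyloTree
) -> tuple[TraitTable, PhyloTree]:
    """Restrict table and tree to their shared species, in table order."""
    table_sp = traits.species
    tree_sp = set(tree.leaf_labels)
    shared = [s for s in table_sp if s in tree_sp]
    if len(shared) < 2:
        raise ValueError(
            "fewer than 2 shared species between table and tree; "
            f"table sample: {table_sp[:5]}, tree sample: {sorted(tree_sp)[:5]}"
        )
    dropped_table = [s for s in table_sp if s not in tree_sp]
    dropped_tree = sorted(tree_sp - set(table_sp))
    if dropped_table:
        logger.info("dropping %d trait records absent from tree: %s",
                    len(dropped_table), dropped_table)
    if dropped_tree:
        logger.info("pruning %d tree taxa absent from table: %s",
                    len(dropped_tree), dropped_tree)
    return traits.restrict(shared), prune(tree, shared)


MissingPolicy = Literal["drop_taxa", "drop_variable", "impute_mode"]


def build_design_matrix(
    traits: TraitTable, missing_policy: MissingPolicy = "drop_taxa"
) -> tuple[DesignMatrix, dict[str, str]]:
    """Intercept + predictor design with the chosen missing-data policy.

    Returns the design and a {species: reason} record of dropped taxa.
    ``drop_taxa`` removes species with any missing predictor, ``drop_variable``
    removes predictors with any missing value, ``impute_mode`` fills missing
    values with the predictor's modal value.
    """
    df = traits.df
    predictors = list(PREDICTORS)
    dropped: dict[str, str] = {}
    if missing_policy == "drop_taxa":
        mask = df[predictors].notna().all(axis=1)
        for sp, row in zip(df["species"], df[predictors].isna().any(axis=1)):
            if row:
                missing = [
                    c for c in predictors
                    if pd.isna(df.loc[df["species"] == sp, c]).any()
                ]
                dropped[sp] = f"missing {', '.join(missing)}"
        df = df[mask]
    elif missing_policy == "drop_variable":
        predictors = [c for c in predictors if df[c].notna().all()]
        removed = sorted(set(PREDICTORS) - set(predictors))
        if removed:
            logger.info("dropping predictors with missing values: %s", removed)
    elif missing_policy == "impute_mode":
        df = df.copy()
        for c in predictors:
            if df[c].isna().any():
                df[c] = df[c].fillna(df[c].mode().iloc[0])
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if dropped:
        logger.info("dropping taxa with missing predictors: %s", dropped)
    dm = DesignMatrix.build(
        df["species"].tolist(),
        {c: df[c].to_numpy(float) for c in predictors},
    )
    return dm, dropped


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisOptions:
    allometric: AllometricParams = AllometricParams()
    missing_policy: MissingPolicy = "drop_taxa"
    use_printed_residuals: bool = False
    pgls: PglsOptions = PglsOptions()


@dataclass
class AnalysisReport:
    residuals: pd.DataFrame
    taxa_used: list[str]
    taxa_dropped: dict[str, str]
    fit: PglsFit
    coefficient_table: pd.DataFrame
    provenance: dict

    def to_text(self) -> str:
        lines = ["# phylogenetic regression of EDP residuals", ""]
        lines.append(f"n_taxa = {self.fit.n_taxa}")
        lam = (
            "indeterminate (star covariance)"
            if self.fit.lambda_indeterminate
            else f"{self.fit.lambda_hat:.6f}"
        )
        lines.append(f"lambda_hat = {lam}")
        lines.append(f"log_likelihood = {self.fit.log_likelihood:.6f}")
        lines.append(f"sigma2_ml = {self.fit.sigma2_hat:.6f}")
        lines.append(f"r_squared = {self.fit.r_squared:.6f}")
        lines.append(
            f"df = {self.fit.df_used} ({self.fit.df_convention}); "
            f"markers use {self.fit.tail}-sided p"
        )
        lines.append("")
        lines.append(self.coefficient_table.to_string(index=False))
        if self.taxa_dropped:
            lines.append("")
            lines.append("dropped taxa:")
            for sp, why in sorted(self.taxa_dropped.items()):
                lines.append(f"  {sp}: {why}")
        lines.append("")
        lines.append("provenance:")
        for k in sorted(self.provenance):
            lines.append(f"  {k} = {self.provenance[k]}")
        return "\n".join(lines) + "\n"


def _coefficient_frame(fit: PglsFit) -> pd.DataFrame:
    rows = coefficient_tests(fit)
    df = pd.DataFrame(
        {
            "variable": fit.names,
            "coefficient": fit.beta,
            "se": fit.se,
            "t": [r[1] for r in rows],
            "p_one_sided": fit.p_one_sided,
            "p_two_sided": fit.p_two_sided,
            "marker": [r[3] for r in rows],
        }
    )
    return df


def _digest(path: str | None) -> str:
    if path is None:
        return "<in-memory>"
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def run_paper_analysis(
    traits: TraitTable,
    tree: PhyloTree,
    options: AnalysisOptions | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Residuals -> design -> reconciliation -> covariance -> PGLS -> report.

    Deterministic given inputs and options.  Stage failures are re-raised
    with the stage name attached.
    """
    from . import __version__

    opts = options or AnalysisOptions()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    if opts.use_printed_residuals:
        if "edpr_printed" not in traits.df.columns:
            raise ValueError(
                "[stage: residuals] use_printed_residuals requires an "
                "edpr_printed column"
            )
        resid_df = traits.df[["species"]].copy()
        resid_df["edp_residual"] = traits.df["edpr_printed"].astype(float)
        resid_df["edp_predicted"] = np.nan
        resid_df["edp_observed"] = traits.df["edp_days"].astype(float)
    else:
        records = stage(
            "residuals", allometry.residual_table, traits, opts.allometric
        )
        resid_df = pd.DataFrame(
            {
                "species": [r.species for r in records],
                "edp_observed": [r.edp_observed for r in records],
                "edp_predicted": [r.edp_predicted for r in records],
                "edp_residual": [r.edp_residual for r in records],
            }
        )

    traits2, tree2 = stage("reconcile", reconcile, traits, tree)
    dm, dropped = stage(
        "design", build_design_matrix, traits2, opts.missing_policy
    )
    if len(dm.labels) < len(traits2):
        tree2 = stage("prune", prune, tree2, dm.labels)
    V = stage("vcv", vcv_matrix, tree2, dm.labels)
    y = (
        resid_df.set_index("species")
        .loc[list(dm.labels), "edp_residual"]
        .to_numpy(float)
    )
    fit = stage("pgls", fit_pgls, y, dm, V, opts.pgls)
    coef = _coefficient_frame(fit)
    logger.info(
        "PGLS fit: n=%d lambda_hat=%s r2=%.4f",
        fit.n_taxa,
        "NA" if fit.lambda_indeterminate else f"{fit.lambda_hat:.6f}",
        fit.r_squared,
    )
    prov = {
        "package_version": __version__,
        "n_input_species": len(traits),
        "missing_policy": opts.missing_policy,
        "use_printed_residuals": opts.use_printed_residuals,
        "allometric_a": opts.allometric.a,
        "allometric_b": opts.allometric.b,
        "df_convention": opts.pgls.df_convention,
        "tail": opts.pgls.tail,
        **(provenance or {}),
    }
    return AnalysisReport(
        residuals=resid_df,
        taxa_used=list(dm.labels),
        taxa_dropped=dropped,
        fit=fit,
        coefficient_table=coef,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Consensus workflow
# ---------------------------------------------------------------------------


def consensus_workflow(
    tree_sample: str | TreeSample,
    outgroup: str,
    burnin_fraction: float = 0.25,
    keep: Iterable[str] | None = None,
    threshold: float = 0.5,
) -> PhyloTree:
    """Burn-in discard -> outgroup rooting -> outgroup pruning -> consensus.

    ``tree_sample`` is a path (Newick one-per-line or a Nexus trees block) or
    an in-memory sample.  Each post-burn-in tree is rooted on ``outgroup``
    and the outgroup is pruned before the strict majority-rule consensus is
    built; ``keep``, when given, prunes the consensus to those species.
    """
    sample = (
        tree_sample
        if isinstance(tree_sample, TreeSample)
        else read_tree_sample(tree_sample)
    )
    logger.info("consensus workflow: %d trees read", len(sample))
    sample = discard_burnin(sample, burnin_fraction)
    logger.info("after %.0f%% burn-in: %d trees", 100 * burnin_fraction,
                len(sample))
    rooted = []
    for i, t in enumerate(sample):
        try:
            rt = root_on_outgroup(t, outgroup)
        except KeyError:
            raise KeyError(
                f"outgroup {outgroup!r} absent from tree {i} of the sample"
            ) from None
        ingroup = [l for l in rt.leaf_labels if l != outgroup]
        rooted.append(prune(rt, ingroup))
    cons = majority_rule_consensus(TreeSample(rooted), threshold)
    logger.info("consensus over %d rooted trees: %d leaves", len(rooted),
                cons.n_leaves)
    if keep is not None:
        cons = prune(cons, keep)
        logger.info("consensus pruned to %d kept species", cons.n_leaves)
    return cons


# ---------------------------------------------------------------------------
# Figure
# ---------------------------------------------------------------------------


def plot_edp_allometry(
    traits: TraitTable,
    path: str,
    params: AllometricParams = AllometricParams(),
) -> None:
    """Observed vs allometrically predicted EDP with the 1:1 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    records = allometry.residual_table(traits, params)
    pred = [r.edp_predicted for r in records]
    obs = [r.edp_observed for r in records]
    fig, ax = plt.subplots(figsize=(5, 5))
    lo = min(min(pred), min(obs)) - 2
    hi = max(max(pred), max(obs)) + 2
    ax.plot([lo, hi], [lo, hi], "-", color="0.5", lw=1, label="1:1")
    ax.plot(pred, obs, "+", color="k")
    ax.set_xlabel("predicted EDP (days)")
    ax.set_ylabel("observed EDP (days)")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
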