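"""Synthetic phylogenies and paired green/senesced leaf datasets with known
ground truth.

The generator emulates the study design that motivates the pipeline: 36
woody desert species in 15 families, split into four Na-regulation groups —
euhalophytes (Eu, foliar Na compartmentalisation), secretohalophytes (Se,
salt glands), pseudohalophytes (Ps, Na exclusion) and glycophytes (Gl) —
with 5-8 tagged individuals per species sampled once green and once
senesced.  Defaults are anchored in published group-level means: green-leaf
element concentrations per group, and true resorption efficiencies derived
from those means at the reference mass-loss correction factor 0.8.

Senesced concentrations invert the mass-loss-corrected RE formula exactly
(senesced = green * (1 - RE) / MLCF), so the estimated RE recovers the true
RE in expectation — exactly, at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ELEMENTS, GROUPS, LeafSample
from .tree import Node, Phylogeny

__all__ = [
    "TABLE_GREEN_MEANS",
    "TABLE_SENESCED_MEANS",
    "STUDY_GROUP_SIZES",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_bm_traits",
    "assign_groups",
    "generate_leaf_dataset",
]

# Published group means (mg g-1) used as generator anchors.
TABLE_GREEN_MEANS = pd.DataFrame(
    {
        "Eu": [28.8, 2.84, 22.2, 53.5, 11.6, 19.0],
        "Se": [21.2, 2.09, 8.19, 24.9, 12.6, 23.9],
        "Ps": [22.8, 2.15, 18.8, 3.19, 7.14, 12.5],
        "Gl": [28.8, 3.31, 22.7, 13.2, 13.1, 11.6],
    },
    index=ELEMENTS,
)
TABLE_SENESCED_MEANS = pd.DataFrame(
    {
        "Eu": [14.4, 1.40, 12.6, 70.2, 12.4, 20.1],
        "Se": [12.7, 1.02, 6.55, 20.3, 12.1, 20.5],
        "Ps": [14.0, 1.25, 10.6, 4.54, 9.43, 15.7],
        "Gl": [18.7, 1.71, 13.3, 20.0, 17.5, 13.8],
    },
    index=ELEMENTS,
)

#: standard errors of the green-leaf group means (mg g-1), same layout
TABLE_GREEN_SE = pd.DataFrame(
    {
        "Eu": [1.1, 0.1, 1.9, 4.7, 0.7, 1.4],
        "Se": [0.6, 0.2, 0.8, 2.0, 0.8, 1.1],
        "Ps": [0.7, 0.1, 1.6, 0.5, 0.7, 1.2],
        "Gl": [2.2, 0.3, 3.6, 2.8, 1.8, 1.6],
    },
    index=ELEMENTS,
)

#: group sizes (species counts) of the motivating field survey
STUDY_GROUP_SIZES = {"Eu": 10, "Se": 5, "Ps": 11, "Gl": 10}


def species_log_sd() -> pd.DataFrame:
    """Species-level lognormal sd per element x group implied by the anchor
    table: CV = SE * sqrt(n) / mean, sd = sqrt(ln(1 + CV^2))."""
    n = pd.Series(STUDY_GROUP_SIZES)
    cv = TABLE_GREEN_SE * np.sqrt(n) / TABLE_GREEN_MEANS
    return np.sqrt(np.log1p(cv**2))

#: reference MLCF at which the default true RE values are derived
#: (midpoint of the default per-species MLCF ~ Uniform(0.6, 1.0))
REFERENCE_MLCF = 0.8

N_FAMILIES = 15  # for 36 species; scaled proportionally otherwise


def group_true_re(reference_mlcf: float = REFERENCE_MLCF) -> pd.DataFrame:
    """True RE fractions per element x group implied by the anchor means."""
    return 1.0 - (TABLE_SENESCED_MEANS / TABLE_GREEN_MEANS) * reference_mlcf


# ---------------------------------------------------------------------- #
# tree and trait simulation
# ---------------------------------------------------------------------- #


def simulate_tree(n_tips: int, seed: int | None = None) -> Phylogeny:
    """Seeded pure-birth (Yule, unit rate) ultrametric tree, depth 1.0.

    Tips are labelled sp001..spNNN in left-to-right order.  Hand-rolled
    rather than delegated so that every terminal branch includes the final
    holding time (no zero-length tip branches, which would make the
    phylogenetic covariance matrix singular).
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    root = Node(length=None)
    tips = []
    for _ in range(2):
        tip = Node(length=0.0, parent=root)
        root.children.append(tip)
        tips.append(tip)
    k = 2
    while True:
        wait = rng.exponential(1.0 / k)
        for tip in tips:
            tip.length += wait
        if k == n_tips:
            break
        idx = int(rng.integers(k))
        split = tips[idx]
        new_tips = []
        for _ in range(2):
            child = Node(length=0.0, parent=split)
            split.children.append(child)
            new_tips.append(child)
        tips[idx : idx + 1] = new_tips
        k += 1
    counter = 0

    def label_tips(node: Node) -> None:
        nonlocal counter
        if not node.children:
            counter += 1
            node.label = f"sp{counter:03d}"
        for child in node.children:
            label_tips(child)

    label_tips(root)
    tree = Phylogeny(root)
    tree.scale_to_depth(1.0)
    return tree


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int | None = None,
    n_traits: int = 1,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Brownian-motion trait evolution on a tree.

    Along each branch the trait increments are Normal with variance
    ``sigma2 * branch_length`` (multivariate with the given trait
    correlation matrix when ``n_traits > 1``).  Returns a species x trait
    DataFrame of tip values.
    """
    if not sigma2 >= 0:
        raise ValueError("sigma2 must be non-negative")
    if correlation is None:
        L = np.eye(n_traits)
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (n_traits, n_traits):
            raise ValueError("correlation matrix shape does not match n_traits")
        try:
            L = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix must be positive-definite") from exc
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {id(tree.root): np.full(n_traits, float(root_value))}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        step = np.sqrt(sigma2 * (node.length or 0.0)) * (L @ rng.standard_normal(n_traits))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip:
            out[node.label] = values[id(node)]
    df = pd.DataFrame.from_dict(out, orient="index", columns=[f"trait{i+1}" for i in range(n_traits)])
    return df.loc[tree.tip_labels]


def assign_groups(
    tree: Phylogeny,
    clustered: bool = True,
    seed: int | None = None,
    sizes: dict[str, int] | None = None,
) -> pd.Series:
    """Assign each species to one of the four Na-regulation groups.

    ``clustered=True`` assigns contiguous blocks of the tree's tip order
    (clades or near-clades), so the group label carries phylogenetic
    signal; ``clustered=False`` shuffles labels uniformly at random.  All
    four groups are non-empty.  Default sizes follow the motivating survey
    (Eu 10, Se 5, Ps 11, Gl 10) at 36 tips, a near-equal split otherwise.
    """
    labels = tree.tip_labels
    n = len(labels)
    if n < len(GROUPS):
        raise ValueError("need at least as many tips as groups")
    if sizes is None:
        if n == 36:
            sizes = dict(STUDY_GROUP_SIZES)
        else:
            base, extra = divmod(n, len(GROUPS))
            sizes = {g: base + (1 if i < extra else 0) for i, g in enumerate(GROUPS)}
    if sum(sizes.values()) != n or min(sizes.values()) < 1:
        raise ValueError("group sizes must be positive and sum to the tip count")
    per_tip = [g for g in GROUPS for _ in range(sizes[g])]
    if not clustered:
        rng = np.random.default_rng(seed)
        per_tip = [per_tip[i] for i in rng.permutation(n)]
    return pd.Series(per_tip, index=labels, name="group")


def _assign_families(tree: Phylogeny, n_families: int) -> pd.Series:
    """Contiguous tip blocks as stand-in family labels (fam01..famNN)."""
    labels = tree.tip_labels
    n = len(labels)
    n_families = max(2, min(n_families, n))
    bounds = np.linspace(0, n, n_families + 1).round().astype(int)
    fam = {}
    for f in range(n_families):
        for i in range(bounds[f], bounds[f + 1]):
            fam[labels[i]] = f"fam{f + 1:02d}"
    return pd.Series(fam, name="family").loc[labels]


# ---------------------------------------------------------------------- #
# ground truth and leaf dataset
# ---------------------------------------------------------------------- #


@dataclass
class SyntheticTruth:
    """The generator's hidden parameters, kept for recovery tests.

    ``true_RE`` holds fractions (species x element); ``green_mean`` the
    species-level expected green concentrations (mg g-1); ``phylo_weight``
    the fraction of the among-species log-concentration spread that follows
    Brownian motion on the tree (the rest is i.i.d.); ``noise_sd`` the
    lognormal sd of individual-level deviations.
    """

    tree: Phylogeny
    group_of: pd.Series
    family_of: pd.Series
    site_of: pd.Series
    true_RE: pd.DataFrame  # species x element, fractions in (-0.5, 1)
    mlcf_of: pd.Series  # species -> (0, 1.2]
    green_mean: pd.DataFrame  # species x element, mg g-1
    ldmc_of: pd.Series
    sla_of: pd.Series
    phylo_weight: float
    noise_sd: float
    seed: int | None

    @classmethod
    def default(
        cls,
        n_species: int = 36,
        seed: int | None = 42,
        clustered: bool = True,
        group_sizes: dict[str, int] | None = None,
        phylo_weight: float = 0.5,
        noise_sd: float = 0.2,
        species_sd: float | pd.DataFrame | None = None,
        re_sd: float = 0.05,
        green_means_by_group: pd.DataFrame | None = None,
        true_re_by_group: pd.DataFrame | None = None,
        tree: Phylogeny | None = None,
    ) -> "SyntheticTruth":
        """Build the stated-world default ground truth.

        ``species_sd`` is the lognormal sd of species-level deviations
        around the group mean: by default the per-element, per-group values
        implied by the anchor table's standard errors (see
        :func:`species_log_sd`); a scalar or an element x group DataFrame
        may be supplied instead.  ``re_sd`` jitters the group-level true RE
        per species.
        """
        rng = np.random.default_rng(seed)
        if tree is None:
            tree = simulate_tree(n_species, seed=None if seed is None else seed + 1)
        species = tree.tip_labels
        n = len(species)
        group_of = assign_groups(
            tree,
            clustered=clustered,
            seed=None if seed is None else seed + 2,
            sizes=group_sizes,
        )
        family_of = _assign_families(tree, round(N_FAMILIES * n / 36))

        # sites: halophyte groups on saline sites, glycophytes on gravel;
        # site count scales with species count at the survey's density of
        # ~2 species per site (36 species over 13 saline + 5 gravel sites)
        n_halo = int((group_of != "Gl").sum())
        n_gl = n - n_halo
        saline = [f"saline{i + 1:02d}" for i in range(min(13, max(2, n_halo // 2)))]
        gravel = [f"gravel{i + 1:02d}" for i in range(min(5, max(1, n_gl // 2)))]
        site_of = {}
        i_sal = i_gra = 0
        for sp in species:
            if group_of[sp] == "Gl":
                site_of[sp] = gravel[i_gra % len(gravel)]
                i_gra += 1
            else:
                site_of[sp] = saline[i_sal % len(saline)]
                i_sal += 1
        site_of = pd.Series(site_of, name="site").loc[species]

        base_green = (
            TABLE_GREEN_MEANS if green_means_by_group is None else green_means_by_group
        )
        base_re = group_true_re() if true_re_by_group is None else true_re_by_group

        # species-level log deviations: phylo_weight of the variance follows
        # BM on the tree, the rest is i.i.d.; one independent field per element.
        # Deviations are demeaned within group (the group anchors are fixed
        # features of the stated world; BM structures the within-group
        # spread) and shifted by -sd^2/2 so the lognormal leaves the group
        # arithmetic mean on its anchor.
        w = float(phylo_weight)
        if not 0.0 <= w <= 1.0:
            raise ValueError("phylo_weight must be in [0, 1]")
        if species_sd is None:
            sd_table = species_log_sd()
        elif np.isscalar(species_sd):
            sd_table = pd.DataFrame(
                float(species_sd), index=ELEMENTS, columns=GROUPS
            )
        else:
            sd_table = pd.DataFrame(species_sd)
        group_idx = {g: np.array([group_of[sp] == g for sp in species]) for g in GROUPS}
        green_mean = {}
        for j, el in enumerate(ELEMENTS):
            bm = simulate_bm_traits(
                tree, sigma2=1.0, seed=None if seed is None else seed + 10 + j
            )["trait1"].to_numpy()
            bm_std = (bm - bm.mean()) / bm.std() if bm.std() > 0 else np.zeros(n)
            iid = rng.standard_normal(n)
            z = np.sqrt(w) * bm_std + np.sqrt(1.0 - w) * iid
            for mask in group_idx.values():
                if mask.any():
                    z[mask] -= z[mask].mean()
            sd_sp = np.array([sd_table.loc[el, group_of[sp]] for sp in species])
            dev = sd_sp * z - sd_sp**2 / 2.0
            base = np.array([base_green.loc[el, group_of[sp]] for sp in species])
            green_mean[el] = base * np.exp(dev)
        green_mean = pd.DataFrame(green_mean, index=species)

        true_re = {}
        for el in ELEMENTS:
            base = np.array([base_re.loc[el, group_of[sp]] for sp in species])
            true_re[el] = np.clip(base + re_sd * rng.standard_normal(n), -0.45, 0.95)
        true_re = pd.DataFrame(true_re, index=species)

        mlcf_of = pd.Series(rng.uniform(0.6, 1.0, n), index=species, name="MLCF")
        # euhalophytes get the thick, water-rich, low-SLA leaves that push
        # succulence past the 500 g m-2 flag
        is_eu = (group_of == "Eu").to_numpy()
        ldmc = np.where(
            is_eu, rng.uniform(0.15, 0.30, n), rng.uniform(0.25, 0.50, n)
        )
        sla = np.where(is_eu, rng.uniform(40, 100, n), rng.uniform(80, 250, n))
        return cls(
            tree=tree,
            group_of=group_of,
            family_of=family_of,
            site_of=site_of,
            true_RE=true_re,
            mlcf_of=mlcf_of,
            green_mean=green_mean,
            ldmc_of=pd.Series(ldmc, index=species, name="LDMC"),
            sla_of=pd.Series(sla, index=species, name="SLA"),
            phylo_weight=w,
            noise_sd=float(noise_sd),
            seed=seed,
        )

    def validate(self) -> None:
        if (self.true_RE >= 1).any().any():
            raise ValueError("true_RE >= 1 would force a negative senesced concentration")
        if (self.green_mean <= 0).any().any():
            raise ValueError("green means must be positive")
        if (self.mlcf_of <= 0).any() or (self.mlcf_of > 1.2).any():
            raise ValueError("MLCF must lie in (0, 1.2]")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "phylo_weight": self.phylo_weight,
            "noise_sd": self.noise_sd,
            "group_of": self.group_of.to_dict(),
            "family_of": self.family_of.to_dict(),
            "site_of": self.site_of.to_dict(),
            "true_RE": self.true_RE.to_dict(),
            "mlcf_of": self.mlcf_of.to_dict(),
            "green_mean": self.green_mean.to_dict(),
            "ldmc_of": self.ldmc_of.to_dict(),
            "sla_of": self.sla_of.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def generate_leaf_dataset(
    truth: SyntheticTruth,
    individuals_per_species: tuple[int, int] | int = (5, 8),
    layout: str = "paired",
    seed: int | None = None,
) -> list[LeafSample]:
    """Draw one paired green/senesced leaf dataset from a ground truth.

    Per species and individual: green concentration = species green mean x
    lognormal(0, noise_sd) per element; senesced concentration = species
    green mean x (1 - true_RE) / MLCF x an independent lognormal — the
    exact inversion of the corrected-RE formula, so estimated RE is
    unbiased for true RE (exact at noise_sd = 0).  The senesced leaf's dry
    mass is the green dry mass times the species MLCF, so mass-based MLCF
    estimates recover the truth.

    ``layout='paired'`` (default) emits a green and a senesced row per
    individual; ``layout='total'`` interprets the individual count as total
    leaves, alternating statuses (for the ambiguous "n leaf samples"
    reading of a survey's sample count).
    """
    truth.validate()
    if layout not in ("paired", "total"):
        raise ValueError(f"unknown layout {layout!r}")
    if isinstance(individuals_per_species, int):
        lo = hi = individuals_per_species
    else:
        lo, hi = individuals_per_species
    if not (1 <= lo <= hi <= 20):
        raise ValueError("individuals_per_species must lie within [1, 20]")
    rng = np.random.default_rng(
        seed if seed is not None else (None if truth.seed is None else truth.seed + 1000)
    )
    samples: list[LeafSample] = []
    for sp in truth.tree.tip_labels:
        n_ind = int(rng.integers(lo, hi + 1))
        m = truth.mlcf_of[sp]
        ldmc, sla = truth.ldmc_of[sp], truth.sla_of[sp]
        for i in range(n_ind):
            statuses = ["green", "senesced"]
            if layout == "total":
                statuses = [statuses[i % 2]]
            dry_green = 0.5 * rng.lognormal(0.0, 0.3)
            for status in statuses:
                conc = {}
                for el in ELEMENTS:
                    noise = rng.lognormal(0.0, truth.noise_sd)
                    if status == "green":
                        conc[el] = truth.green_mean.loc[sp, el] * noise
                    else:
                        conc[el] = (
                            truth.green_mean.loc[sp, el]
                            * (1.0 - truth.true_RE.loc[sp, el])
                            / m
                            * noise
                        )
                dry = dry_green if status == "green" else dry_green * m
                samples.append(
                    LeafSample(
                        species=sp,
                        family=truth.family_of[sp],
                        group=truth.group_of[sp],
                        site=truth.site_of[sp],
                        individual=f"ind{i + 1:02d}",
                        status=status,
                        conc=conc,
                        leaf_area=sla * dry,
                        dry_mass=dry,
                        saturated_mass=dry / ldmc,
                    )
                )
    return samples
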