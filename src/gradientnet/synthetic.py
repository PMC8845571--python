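"""Synthetic study generator: nested sampling design along a pH gradient,
Ricker dynamics of an aluminum-tolerant sub-community, and functional-gene
signals tied to designated taxa.

The generator emulates the statistical structure of a continental paddy-soil
survey: samples nested as region / field / subsample, soil pH spanning the
acid-to-alkaline range, exchangeable Al3+ decaying exponentially with pH, a
sparse signed interaction matrix driving the tolerant taxa along the acidic
part of the gradient, and gene-array signals that mix the abundances of the
taxa they are linked to.  Everything downstream of the field survey
(identification, series building, inference, niche and association analyses)
can therefore be exercised against a known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "sample_design",
    "simulate_ricker",
    "make_interactions",
    "assemble_dataset",
]

# Genera used as source organisms of Al-resistance probes; tolerant OTUs are
# drawn from this pool so that gene-based identification can recover them.
TOLERANT_GENERA = (
    "Clostridium",
    "Bacillus",
    "Paenibacillus",
    "Desulfitobacterium",
    "Desulfosporosinus",
    "Burkholderia",
    "Pseudomonas",
    "Serratia",
    "Klebsiella",
    "Stenotrophomonas",
    "Enterobacter",
    "Rhodotorula",
)

AL_RESISTANCE_FAMILIES = (
    "AANH_like",
    "AAT_I",
    "Alr1p_like",
    "YnbB",
    "Beta_elim_lyase",
    "MetC",
    "QueC",
    "Met_gamma_lyase",
)

ANTIOXIDANT_FAMILIES = (
    "cat_arc",
    "cat_bac",
    "cat_fun",
    "per_arc",
    "per_bac",
    "per_fun",
    "sod_CuZn",
    "sod_FeMn",
    "sod_nickel",
)

# covariate -> (intercept, slope vs pH, noise sd); slopes give the broad
# climatic/edaphic correlations of a north(alkaline)-south(acidic) transect.
COVARIATE_MODEL = {
    "MAT": (40.0, -3.0, 1.5),
    "MAP": (3200.0, -300.0, 120.0),
    "OM": (60.0, -5.0, 4.0),
    "DOC": (300.0, -25.0, 20.0),
    "TN": (3.5, -0.25, 0.25),
    "TP": (1.2, -0.05, 0.1),
    "AP": (40.0, -2.5, 4.0),
    "TK": (15.0, 0.5, 1.5),
    "AK": (150.0, 5.0, 20.0),
    "CEC": (2.0, 2.0, 1.5),
    "DON": (30.0, -2.0, 3.0),
    "DTN": (45.0, -2.5, 3.5),
    "NH4_N": (25.0, -1.5, 2.5),
    "NO3_N": (10.0, 0.8, 1.5),
}

# fixed offsets expanding the global seed into per-stage child streams
_STAGE_OFFSETS = {
    "design": 11,
    "interactions": 23,
    "dynamics": 37,
    "baseline": 53,
    "counts": 71,
    "genes": 89,
    "taxonomy": 101,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE_OFFSETS[stage], int(seed)])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generative parameters.

    Defaults reproduce the survey scale the package targets: 13 regions x 3
    fields x 11 subsamples = 429 samples over pH 3.6-8.7, rarefaction-scale
    read depths, and a sparse interaction matrix among the tolerant taxa.
    """

    n_regions: int = 13
    fields_per_region: int = 3
    subsamples_per_field: int = 11
    ph_range: tuple[float, float] = (3.6, 8.7)
    # Al3+ = a * exp(-b * pH) * lognormal(0, sigma)
    al_decay: tuple[float, float, float] = (4000.0, 1.5, 0.6)
    n_taxa: int = 120
    n_tolerant: int = 12
    interaction_density: float = 0.08
    interaction_scale: float = 1.2
    process_noise_sd: float = 0.15
    read_depth: tuple[int, int] = (20000, 30000)
    seed: int = 0
    field_ph_sd: float = 0.18
    subsample_ph_sd: float = 0.12
    tolerant_mass: float = 0.7
    acid_threshold: float = 5.1
    ph_step: float = 0.01

    def validate(self) -> None:
        for name in ("n_regions", "fields_per_region", "subsamples_per_field",
                     "n_taxa", "n_tolerant"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"configuration error: {name} must be >= 1")
        if self.n_tolerant > self.n_taxa:
            raise ValueError("configuration error: n_tolerant exceeds n_taxa")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValueError(
                "configuration error: interaction_density must lie in [0, 1]")
        if not self.ph_range[0] < self.ph_range[1]:
            raise ValueError("configuration error: ph_range must be increasing")
        if self.read_depth[0] < 1 or self.read_depth[1] < self.read_depth[0]:
            raise ValueError("configuration error: read_depth must be a "
                             "non-empty positive range")
        if not 0.0 < self.tolerant_mass < 1.0:
            raise ValueError("configuration error: tolerant_mass must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted structure that downstream stages are expected to recover."""

    taxa: list[str]                     # tolerant taxa, order of true_interactions
    true_interactions: np.ndarray       # signed, taxa x taxa, A[i, j] = effect of j on i
    growth_rates: np.ndarray
    true_roles: dict[str, str]          # taxon -> influential/sensitive/bidirectional/orphan
    tolerant_set: set[str]
    gene_taxon_links: list[tuple[str, str]]

    def to_json(self, path) -> None:
        payload = {
            "taxa": list(self.taxa),
            "true_interactions": np.asarray(self.true_interactions).tolist(),
            "growth_rates": np.asarray(self.growth_rates).tolist(),
            "true_roles": self.true_roles,
            "tolerant_set": sorted(self.tolerant_set),
            "gene_taxon_links": [list(p) for p in self.gene_taxon_links],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            taxa=payload["taxa"],
            true_interactions=np.asarray(payload["true_interactions"], dtype=float),
            growth_rates=np.asarray(payload["growth_rates"], dtype=float),
            true_roles=payload["true_roles"],
            tolerant_set=set(payload["tolerant_set"]),
            gene_taxon_links=[tuple(p) for p in payload["gene_taxon_links"]],
        )


def sample_design(config: SimulationConfig) -> pd.DataFrame:
    """Generate sample metadata for the nested region/field/subsample design.

    Region mean pH values sit on an equally spaced grid over ``ph_range``
    (the transect); field means jitter around the region mean and subsamples
    around the field mean.  Exchangeable Al3+ follows
    ``a * exp(-b * pH) * lognormal(0, sigma)`` and each climatic/edaphic
    covariate is a linear-in-pH trend plus Gaussian noise.

    Returns a DataFrame indexed by sample id with columns
    ``region, field, pH, Al`` plus the covariates.
    """
    config.validate()
    rng = _stage_rng(config.seed, "design")
    lo, hi = config.ph_range
    region_means = np.linspace(lo, hi, config.n_regions)

    rows = []
    for r, mu_region in enumerate(region_means):
        for f in range(config.fields_per_region):
            mu_field = mu_region + rng.normal(0.0, config.field_ph_sd)
            for s in range(config.subsamples_per_field):
                ph = mu_field + rng.normal(0.0, config.subsample_ph_sd)
                ph = float(np.clip(ph, lo, hi))
                ph = round(ph, 2)  # field pH meters read to 0.01
                rows.append({
                    "sample": f"R{r + 1:02d}F{f + 1}S{s + 1:02d}",
                    "region": f"R{r + 1:02d}",
                    "field": f"R{r + 1:02d}F{f + 1}",
                    "pH": ph,
                })
    meta = pd.DataFrame(rows).set_index("sample")

    a, b, sigma = config.al_decay
    eps = np.exp(rng.normal(0.0, sigma, size=len(meta))) if sigma > 0 else 1.0
    meta["Al"] = a * np.exp(-b * meta["pH"].to_numpy()) * eps

    for name, (alpha, beta, sd) in COVARIATE_MODEL.items():
        noise = rng.normal(0.0, sd, size=len(meta)) if sd > 0 else 0.0
        meta[name] = alpha + beta * meta["pH"].to_numpy() + noise
    return meta


def simulate_ricker(
    A: np.ndarray,
    r: np.ndarray,
    x0: np.ndarray,
    steps: int,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Simulate discrete Ricker dynamics x(t+1) = x(t) * exp(r + A x(t) + eps).

    ``A[i, j]`` is the per-capita effect of taxon j on the log-growth of
    taxon i; ``eps`` is iid Gaussian process noise.  Returns a strictly
    positive (n_taxa, steps) array whose first column is ``x0``.
    """
    A = np.asarray(A, dtype=float)
    r = np.broadcast_to(np.asarray(r, dtype=float), (A.shape[0],)).copy()
    x0 = np.asarray(x0, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("interaction matrix A must be square")
    if x0.shape != (A.shape[0],) or np.any(x0 <= 0):
        raise ValueError("x0 must be strictly positive with one entry per taxon")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = np.empty((A.shape[0], steps))
    out[:, 0] = x0
    for t in range(steps - 1):
        growth = r + A @ out[:, t]
        if noise_sd > 0:
            growth = growth + rng.normal(0.0, noise_sd, size=A.shape[0])
        # clip the log-growth so a badly conditioned matrix cannot overflow
        out[:, t + 1] = out[:, t] * np.exp(np.clip(growth, -20.0, 20.0))
    return out


def make_interactions(
    n: int,
    density: float,
    scale: float,
    rng: np.random.Generator,
    self_limitation: float = -0.25,
    equilibrium_range: tuple[float, float] = (0.7, 1.3),
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a sparse signed interaction matrix with a stable equilibrium.

    Diagonal entries are fixed negative (self-limitation); off-diagonal
    entries are placed uniformly at the requested density with magnitudes
    uniform in [0.2, 0.4] * scale and random sign.  Rather than rejecting on
    the equilibrium, a positive equilibrium x* is drawn first and the growth
    rates set to r = -A x*, which makes x* an equilibrium by construction;
    candidates are only rejected when the linearised update I + diag(x*) A
    is not a stable map, so the planted dynamics neither crash nor explode.
    """
    n_slots = n * (n - 1)
    n_edges = int(round(density * n_slots))
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for _ in range(max_tries):
        A = np.diag(np.full(n, self_limitation))
        if n_edges > 0:
            picks = rng.choice(len(slots), size=n_edges, replace=False)
            for k in picks:
                i, j = slots[k]
                mag = rng.uniform(0.2, 0.4) * scale
                A[i, j] = mag * rng.choice([-1.0, 1.0])
        x_star = rng.uniform(*equilibrium_range, size=n)
        r = -A @ x_star
        jac = np.eye(n) + x_star[:, None] * A
        if np.max(np.abs(np.linalg.eigvals(jac))) < 0.98:
            return A, r
    raise RuntimeError("could not draw a stable interaction matrix; "
                       "lower interaction_density or interaction_scale")


def _roles_from_matrix(A: np.ndarray, taxa: list[str]) -> dict[str, str]:
    """Role labels implied by the nonzero off-diagonal pattern of ``A``."""
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    out_deg = (off != 0).sum(axis=0)   # column j: edges j -> i
    in_deg = (off != 0).sum(axis=1)    # row i
    roles = {}
    for k, t in enumerate(taxa):
        if out_deg[k] > 0 and in_deg[k] == 0:
            roles[t] = "influential"
        elif in_deg[k] > 0 and out_deg[k] == 0:
            roles[t] = "sensitive"
        elif in_deg[k] > 0 and out_deg[k] > 0:
            roles[t] = "bidirectional"
        else:
            roles[t] = "orphan"
    return roles


def _ph_grid(meta: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Equally spaced 0.01-pH grid covering the acidic samples."""
    acid = meta.loc[meta["pH"] < config.acid_threshold, "pH"]
    if acid.empty:
        return np.empty(0)
    step = config.ph_step
    k0 = int(np.floor(acid.min() / step + 0.5))
    k1 = int(np.floor(acid.max() / step + 0.5))
    return np.arange(k0, k1 + 1) * step


def assemble_dataset(config: SimulationConfig | None = None):
    """Generate the full input bundle plus ground truth.

    Returns ``(otu_table, taxonomy, genes, metadata, truth)`` where

    - ``otu_table``: samples x OTUs integer counts (multinomial at a per-sample
      depth drawn from ``read_depth``);
    - ``taxonomy``: OTU -> domain..genus; tolerant OTUs carry genera from the
      Al-resistance probe source pool, others a disjoint genus pool;
    - ``genes``: probe table (family, category, source_genus, one signal
      column per sample);
    - ``metadata``: the `sample_design` output;
    - ``truth``: planted interactions, roles, tolerant set and gene links.

    Tolerant taxa follow Ricker dynamics along the acidic (pH < 5.1) grid —
    a sample's tolerant profile is the trajectory value at its rounded pH
    step — and keep a low lognormal baseline elsewhere.  Non-tolerant taxa
    follow a neutral lognormal baseline everywhere.  Antioxidant-gene signals
    are linear mixes of the relative abundances of the influential taxa they
    are linked to, plus Gaussian noise.
    """
    config = config or SimulationConfig()
    config.validate()
    meta = sample_design(config)

    n, n_tol = config.n_taxa, config.n_tolerant
    otu_ids = [f"OTU_{k + 1:05d}" for k in range(n)]

    rng_tax = _stage_rng(config.seed, "taxonomy")
    tol_idx = np.sort(rng_tax.choice(n, size=n_tol, replace=False))
    tol_ids = [otu_ids[k] for k in tol_idx]
    tol_mask = np.zeros(n, dtype=bool)
    tol_mask[tol_idx] = True

    genera = np.array([f"Genus_{k + 1:03d}" for k in range(n)], dtype=object)
    genera[tol_idx] = rng_tax.choice(TOLERANT_GENERA, size=n_tol)
    taxonomy = pd.DataFrame({
        "domain": "Bacteria",
        "phylum": np.where(tol_mask, "Firmicutes", "Proteobacteria"),
        "class": "Unclassified",
        "order": "Unclassified",
        "family": "Unclassified",
        "genus": genera,
    }, index=pd.Index(otu_ids, name="otu"))

    # planted interactions among tolerant taxa
    rng_int = _stage_rng(config.seed, "interactions")
    A, r = make_interactions(n_tol, config.interaction_density,
                             config.interaction_scale, rng_int)
    roles = _roles_from_matrix(A, tol_ids)

    # Ricker trajectory along the acidic pH grid; a survey with (almost) no
    # acidic samples still gets a valid (constant-equilibrium) block
    grid = _ph_grid(meta, config)
    rng_dyn = _stage_rng(config.seed, "dynamics")
    x_star = np.linalg.solve(-A, r)
    x0 = x_star * np.exp(rng_dyn.normal(0.0, 0.2, size=n_tol))
    if len(grid) >= 2:
        traj = simulate_ricker(A, r, x0, steps=len(grid),
                               noise_sd=config.process_noise_sd, seed=rng_dyn)
    else:
        traj = np.tile(x_star[:, None], (1, max(len(grid), 1)))
    step_of = {int(np.floor(g / config.ph_step + 0.5)): t
               for t, g in enumerate(grid)}

    # neutral lognormal baseline (relative weights within the non-tolerant
    # remainder of each sample, and tolerant baselines outside acidic soils)
    rng_base = _stage_rng(config.seed, "baseline")
    log_mean = rng_base.normal(0.0, 1.2, size=n)
    weights = np.exp(log_mean[None, :] +
                     rng_base.normal(0.0, 0.2, size=(len(meta), n)))

    # the planted trajectory maps to relative abundances directly:
    # p_i(t) = c * x_i(t) with one global scale c chosen so the tolerant
    # block carries ~tolerant_mass of the acidic community; the neutral
    # baseline fills the remainder.  Keeping the map linear (no per-sample
    # renormalisation of the block) preserves the Ricker relation on the
    # relative-abundance scale the downstream analyses observe.
    acid_mask = (meta["pH"] < config.acid_threshold).to_numpy()
    c_scale = config.tolerant_mass / traj.sum(axis=0).mean()
    if c_scale * traj.sum(axis=0).max() > 0.9:
        c_scale = 0.9 / traj.sum(axis=0).max()

    props = np.zeros_like(weights)
    for s, (is_acid, ph) in enumerate(zip(acid_mask, meta["pH"].to_numpy())):
        if is_acid:
            t = step_of[int(np.floor(ph / config.ph_step + 0.5))]
            tol_prop = c_scale * traj[:, t]
        else:
            # tolerant taxa persist at a low, patchy baseline elsewhere
            w = weights[s, tol_idx]
            tol_prop = 0.05 * w / w.sum()
        props[s, tol_idx] = tol_prop
        w_nt = weights[s, ~tol_mask]
        props[s, ~tol_mask] = (1.0 - tol_prop.sum()) * w_nt / w_nt.sum()

    # multinomial read counts at a per-sample depth
    rng_cnt = _stage_rng(config.seed, "counts")
    lo_d, hi_d = config.read_depth
    depths = rng_cnt.integers(lo_d, hi_d + 1, size=len(meta))
    counts = np.vstack([rng_cnt.multinomial(d, p)
                        for d, p in zip(depths, props)])
    otu_table = pd.DataFrame(counts, index=meta.index.copy(), columns=otu_ids)

    # gene-probe table: Al-resistance probes define the tolerant genus pool;
    # antioxidant probes mix the influential taxa they are linked to
    rng_gene = _stage_rng(config.seed, "genes")
    probes = []
    tol_genera = sorted(set(genera[tol_idx]))
    for k, fam in enumerate(AL_RESISTANCE_FAMILIES):
        for g in tol_genera:
            probes.append((f"alr_{k + 1:02d}_{g}", fam, "al_resistance", g))
    influential = [t for t, role in roles.items() if role in
                   ("influential", "bidirectional")] or tol_ids
    links: list[tuple[str, str]] = []
    anti_rows = []
    for k, fam in enumerate(ANTIOXIDANT_FAMILIES):
        probe = f"aox_{k + 1:02d}_{fam}"
        n_links = int(rng_gene.integers(1, min(3, len(influential)) + 1))
        chosen = list(rng_gene.choice(influential, size=n_links, replace=False))
        links.extend((probe, t) for t in chosen)
        anti_rows.append((probe, fam, "antioxidant",
                          taxonomy.loc[chosen[0], "genus"], chosen))

    signal_cols = {}
    rel = props  # true relative abundances, pre-sequencing
    col_of = {t: j for j, t in enumerate(otu_ids)}
    gene_index, gene_meta = [], []
    for probe, fam, cat, genus in probes:
        # Al-resistance probe signal tracks its source genus' total abundance
        members = [j for j, g in enumerate(genera) if g == genus and tol_mask[j]]
        sig = rel[:, members].sum(axis=1) if members else np.zeros(len(meta))
        sig = sig + np.abs(rng_gene.normal(0.0, 0.002, size=len(meta)))
        gene_index.append(probe)
        gene_meta.append((fam, cat, genus))
        signal_cols[probe] = sig
    for probe, fam, cat, genus, chosen in anti_rows:
        sig = sum(rel[:, col_of[t]] for t in chosen)
        sig = sig + np.abs(rng_gene.normal(0.0, 0.002, size=len(meta)))
        gene_index.append(probe)
        gene_meta.append((fam, cat, genus))
        signal_cols[probe] = sig

    genes = pd.DataFrame(
        gene_meta, index=pd.Index(gene_index, name="probe"),
        columns=["family", "category", "source_genus"],
    )
    sig_mat = pd.DataFrame(signal_cols, index=meta.index).T
    genes = pd.concat([genes, sig_mat], axis=1)

    truth = GroundTruth(
        taxa=tol_ids,
        true_interactions=A,
        growth_rates=r,
        true_roles=roles,
        tolerant_set=set(tol_ids),
        gene_taxon_links=links,
    )
    return otu_table, taxonomy, genes, meta, truth


def write_dataset(outdir, otu_table, taxonomy, genes, metadata, truth) -> None:
    """Write the bundle as plain TSV/JSON files (OTUs as rows for the table)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    otu_table.T.to_csv(outdir / "otu_table.tsv", sep="\t", index_label="otu")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    genes.to_csv(outdir / "genes.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    truth.to_json(outdir / "ground_truth.json")
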