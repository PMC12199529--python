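"""Synthetic genus-level count tables with a known latent correlation network.

The generator follows a logistic-normal-multinomial scheme: per-sample latent
log-abundances are drawn from a multivariate normal whose correlation matrix
carries a planted edge structure (modules plus designated hub genera),
exponentiated, closed to a composition and finally observed through a
multinomial read-count draw.  Every dataset therefore comes with a ground
truth -- the basis correlation matrix, the module assignment and the planted
hub set -- against which downstream network inference can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BasisNetworkSpec",
    "DepthLaw",
    "GroundTruth",
    "SyntheticDataset",
    "generate_basis_correlation",
    "sample_counts",
    "generate_case_control",
    "write_dataset",
]

#: planted correlations with magnitude below this are not counted as edges
EDGE_TOLERANCE = 1e-3

#: eigenvalue floor used when repairing an indefinite raw correlation matrix
PD_EIGEN_FLOOR = 1e-6


@dataclass(frozen=True)
class BasisNetworkSpec:
    """Parameters of the planted basis-correlation network.

    Defaults mirror the scale of a genus-level 16S survey after filtering:
    87 genera organised into a handful of correlated modules with sparse
    between-module edges and a few high-degree hub genera.
    """

    n_genera: int = 87
    n_modules: int = 5
    p_within: float = 0.3
    p_between: float = 0.01
    hub_ids: tuple[int, ...] = ()
    hub_extra_degree: int = 0
    corr_magnitude_range: tuple[float, float] = (0.4, 0.7)
    negative_edge_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera < 2:
            raise ValueError("n_genera must be at least 2")
        if self.n_modules < 1 or self.n_modules > self.n_genera:
            raise ValueError("n_modules must be in [1, n_genera]")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        lo, hi = self.corr_magnitude_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("corr_magnitude_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.negative_edge_fraction <= 1.0):
            raise ValueError("negative_edge_fraction must be in [0, 1]")
        if self.hub_extra_degree < 0 or self.hub_extra_degree > self.n_genera - 1:
            raise ValueError("hub_extra_degree must be in [0, n_genera - 1]")
        bad = [h for h in self.hub_ids if not (0 <= h < self.n_genera)]
        if bad:
            raise ValueError(f"hub_ids out of range: {bad}")


@dataclass(frozen=True)
class DepthLaw:
    """Per-sample read-depth distribution with a hard floor.

    ``kind`` is ``"lognormal"`` (mean read depth ``mean``, log-scale sigma
    ``sigma``, truncated below at ``floor``) or ``"constant"`` (every sample
    sequenced at exactly ``mean`` reads).  The default emulates stool 16S
    libraries: around 30,000 reads, never below the 10,000-read sample filter.
    """

    kind: str = "lognormal"
    mean: float = 30_000.0
    sigma: float = 0.4
    floor: int = 10_000

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, int(self.mean), dtype=np.int64)
        if self.kind != "lognormal":
            raise ValueError(f"unknown depth law kind: {self.kind!r}")
        mu = np.log(self.mean) - 0.5 * self.sigma**2
        depths = rng.lognormal(mu, self.sigma, size=n)
        return np.maximum(np.round(depths), self.floor).astype(np.int64)


@dataclass
class GroundTruth:
    """Planted basis correlation structure of one sample group."""

    basis_correlation: np.ndarray
    module_of: np.ndarray          # genus index -> module id
    true_hubs: frozenset[int]
    true_edges: frozenset[tuple[int, int]]
    #: the drawn adjacency before any positive-definiteness repair
    planted_edges: frozenset[tuple[int, int]] = frozenset()

    @property
    def n_genera(self) -> int:
        return self.basis_correlation.shape[0]


@dataclass
class SyntheticDataset:
    """Counts plus metadata plus per-group ground truth."""

    counts: pd.DataFrame           # genus x sample, integer
    group_of: pd.Series            # sample id -> group label
    truth_per_group: dict[str, GroundTruth]
    read_depths: pd.Series
    seed: int


def _planted_adjacency(spec: BasisNetworkSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Module-structured random adjacency with extra edges attached to hubs."""
    n = spec.n_genera
    module_of = np.arange(n) % spec.n_modules
    same = module_of[:, None] == module_of[None, :]
    prob = np.where(same, spec.p_within, spec.p_between)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    adj = upper | upper.T
    np.fill_diagonal(adj, False)
    for hub in spec.hub_ids:
        non_neighbors = np.flatnonzero(~adj[hub])
        non_neighbors = non_neighbors[non_neighbors != hub]
        k = min(spec.hub_extra_degree, non_neighbors.size)
        for j in rng.choice(non_neighbors, size=k, replace=False):
            adj[hub, j] = adj[j, hub] = True
    return adj, module_of


def _nearest_pd_correlation(raw: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and re-standardise to unit diagonal."""
    vals, vecs = np.linalg.eigh(raw)
    if vals.min() > PD_EIGEN_FLOOR:
        return raw
    vals = np.clip(vals, PD_EIGEN_FLOOR, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def generate_basis_correlation(spec: BasisNetworkSpec) -> GroundTruth:
    """Draw a positive-definite correlation matrix with planted edges.

    Edge magnitudes are uniform on ``corr_magnitude_range``; a
    ``negative_edge_fraction`` of them are negated.  If the raw matrix is not
    positive definite it is repaired by eigenvalue clipping followed by
    re-standardisation, and the planted edge set is re-derived from the
    repaired matrix above :data:`EDGE_TOLERANCE` so that "truth" always refers
    to the matrix actually used for sampling.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    adj, module_of = _planted_adjacency(spec, rng)
    n = spec.n_genera
    lo, hi = spec.corr_magnitude_range

    rho = np.zeros((n, n))
    iu, ju = np.where(np.triu(adj, k=1))
    mags = rng.uniform(lo, hi, size=iu.size)
    signs = np.where(rng.random(iu.size) < spec.negative_edge_fraction, -1.0, 1.0)
    rho[iu, ju] = rho[ju, iu] = mags * signs
    np.fill_diagonal(rho, 1.0)

    planted = frozenset((int(a), int(b)) for a, b in zip(iu, ju))
    rho = _nearest_pd_correlation(rho)
    ii, jj = np.where(np.triu(np.abs(rho) > EDGE_TOLERANCE, k=1))
    edges = frozenset((int(a), int(b)) for a, b in zip(ii, jj))
    return GroundTruth(
        basis_correlation=rho,
        module_of=module_of,
        true_hubs=frozenset(int(h) for h in spec.hub_ids),
        true_edges=edges,
        planted_edges=planted,
    )


def sample_counts(
    truth: GroundTruth,
    n_samples: int,
    mean_log_abundance: np.ndarray | None = None,
    log_abundance_sd: float | np.ndarray = 1.0,
    depth_law: DepthLaw | None = None,
    seed: int = 0,
    group_label: str = "group",
) -> SyntheticDataset:
    """Draw a single-group count table from the latent correlation model.

    Per sample a latent log-abundance vector is drawn from
    ``MVN(mean_log_abundance, diag(sd) R diag(sd))`` with ``R`` the planted
    basis correlation, exponentiated, closed to a composition and observed via
    a multinomial draw at the sample's read depth.  Zeros arise only through
    the multinomial.  When ``mean_log_abundance`` is omitted, genus means are
    drawn once from ``N(0, 2^2)``, giving the several-orders-of-magnitude
    unevenness (and hence substantial zero fraction) typical of gut genera.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    n = truth.n_genera
    rng = np.random.default_rng(seed)
    depth_law = depth_law or DepthLaw()

    if mean_log_abundance is None:
        mean_log_abundance = rng.normal(0.0, 2.0, size=n)
    mu = np.asarray(mean_log_abundance, dtype=float)
    if mu.shape != (n,):
        raise ValueError("mean_log_abundance must have one entry per genus")
    sd = np.broadcast_to(np.asarray(log_abundance_sd, dtype=float), (n,))
    cov = truth.basis_correlation * np.outer(sd, sd)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent covariance is not positive definite") from exc

    latent = mu + rng.standard_normal((n_samples, n)) @ chol.T
    comp = np.exp(latent)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = depth_law.draw(n_samples, rng)
    counts = np.empty((n, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], comp[s])

    genus_ids = [f"g{i:03d}" for i in range(n)]
    sample_ids = [f"{group_label}_s{j:04d}" for j in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=genus_ids, columns=sample_ids)
    group = pd.Series(group_label, index=sample_ids, name="group")
    return SyntheticDataset(
        counts=counts_df,
        group_of=group,
        truth_per_group={group_label: truth},
        read_depths=pd.Series(depths, index=sample_ids, name="depth"),
        seed=seed,
    )


def generate_case_control(
    spec_a: BasisNetworkSpec,
    spec_b: BasisNetworkSpec,
    n_a: int = 365,
    n_b: int = 522,
    seed: int = 0,
    labels: tuple[str, str] = ("control", "case"),
    depth_law: DepthLaw | None = None,
    shared_mean_log_abundance: bool = True,
) -> SyntheticDataset:
    """Two-group dataset with group-specific planted topology.

    Group sizes default to the case-control design the generator emulates
    (365 controls, 522 cases).  With ``shared_mean_log_abundance`` both groups
    use the same per-genus mean log-abundances (drawn once), so the groups
    differ only in correlation structure, not in marginal composition.
    """
    if spec_a.n_genera != spec_b.n_genera:
        raise ValueError("both specs must share n_genera")
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be positive")
    ss = np.random.SeedSequence(seed)
    seed_mu, seed_a, seed_b = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    mu = (
        np.random.default_rng(seed_mu).normal(0.0, 2.0, size=spec_a.n_genera)
        if shared_mean_log_abundance
        else None
    )
    truth_a = generate_basis_correlation(spec_a)
    truth_b = generate_basis_correlation(spec_b)
    ds_a = sample_counts(truth_a, n_a, mu, depth_law=depth_law, seed=seed_a, group_label=labels[0])
    ds_b = sample_counts(truth_b, n_b, mu, depth_law=depth_law, seed=seed_b, group_label=labels[1])
    counts = pd.concat([ds_a.counts, ds_b.counts], axis=1)
    return SyntheticDataset(
        counts=counts,
        group_of=pd.concat([ds_a.group_of, ds_b.group_of]),
        truth_per_group={labels[0]: truth_a, labels[1]: truth_b},
        read_depths=pd.concat([ds_a.read_depths, ds_b.read_depths]),
        seed=seed,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path, spec: BasisNetworkSpec | None = None) -> dict[str, Path]:
    """Write counts/metadata/truth TSVs plus a JSON sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "sidecar": outdir / "dataset.json",
    }
    ds.counts.to_csv(paths["counts"], sep="\t", index_label="genus")
    meta = pd.DataFrame({"sample_id": ds.group_of.index, "group": ds.group_of.values})
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    for label, truth in ds.truth_per_group.items():
        p = outdir / f"true_edges_{label}.tsv"
        rows = [
            (f"g{i:03d}", f"g{j:03d}", truth.basis_correlation[i, j])
            for i, j in sorted(truth.true_edges)
        ]
        pd.DataFrame(rows, columns=["genus_i", "genus_j", "rho"]).to_csv(p, sep="\t", index=False)
        paths[f"true_edges_{label}"] = p
    sidecar = {"seed": ds.seed, "groups": {k: sorted(t.true_hubs) for k, t in ds.truth_per_group.items()}}
    if spec is not None:
        sidecar["spec"] = dataclasses.asdict(spec)
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths
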