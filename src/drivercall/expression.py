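"""Single-sample differential expression and the RNA feature block.

Differential expression is usually a cohort-level exercise; here each tumor
sample is contrasted individually against the pooled normal samples so the
resulting logFC/logCPM values can serve as per-patient features. Because a
single tumor sample carries no replication, the negative-binomial
dispersion cannot be estimated per contrast; instead a common biological
coefficient of variation (BCV = sqrt(dispersion)) is estimated once from
the whole cohort and reused for every single-sample contrast, including
future samples scored against a frozen cohort model.

Normalization is plain counts-per-million with library-size offsets; the
prior count stabilizes log fold changes of low-abundance genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom

from .config import RunConfig
from .io import CountsMatrix, NORMAL, TUMOR
from .network import NodeStats

logger = logging.getLogger(__name__)

_PHI_LO, _PHI_HI = 1e-6, 4.0


@dataclass
class DispersionEstimate:
    """Common negative-binomial dispersion phi and its BCV = sqrt(phi)."""

    phi: float
    bcv: float
    n_genes_used: int
    at_boundary: bool = False


@dataclass
class DEGProfile:
    """Per-gene logFC/logCPM for one tumor sample vs pooled normals."""

    sample_id: str
    genes: list[str]
    logfc: np.ndarray
    logcpm: np.ndarray
    p_value: np.ndarray
    is_deg: np.ndarray  # |logFC| > tau

    def logfc_map(self) -> dict[str, float]:
        return dict(zip(self.genes, self.logfc))


def cpm_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million for every sample; fatal on a zero library size."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        zeros = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples {zeros}")
    return counts / libsize * 1e6


def cpm(counts: CountsMatrix, sample: str) -> pd.Series:
    return cpm_matrix(counts.counts)[sample]


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Summed NB log-likelihood with size r = 1/phi; handles mu == 0 cells."""
    r = 1.0 / phi
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    safe_mu = np.where(mu > 0, mu, 1.0)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + safe_mu))
        + y * np.log(safe_mu / (r + safe_mu))
    )
    # mu == 0: P(Y=0) = 1, any positive count is impossible
    ll = np.where(mu > 0, ll, np.where(y == 0, 0.0, -np.inf))
    return float(ll.sum())


def estimate_common_bcv(counts: CountsMatrix) -> DispersionEstimate:
    """Estimate the cohort-wide common dispersion from tumor-vs-normal counts.

    Under a two-group means model with library-size offsets, the group mean
    rates are profiled out (ratio estimator per gene and condition) and the
    common dispersion phi maximizes the summed NB log-likelihood across all
    genes, by bounded 1-D search on log(phi) over [1e-6, 4].
    """
    tumor, normal = counts.tumor_samples, counts.normal_samples
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need at least two samples per condition to estimate BCV")
    mat = counts.counts
    keep = mat.sum(axis=1) > 0
    mat = mat.loc[keep]
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("all genes have zero counts")

    libsize = counts.counts.sum(axis=0)
    y_t = mat[tumor].to_numpy(dtype=float)
    y_n = mat[normal].to_numpy(dtype=float)
    N_t = libsize[tumor].to_numpy(dtype=float)
    N_n = libsize[normal].to_numpy(dtype=float)
    q_t = y_t.sum(axis=1) / N_t.sum()
    q_n = y_n.sum(axis=1) / N_n.sum()
    mu_t = np.outer(q_t, N_t)
    mu_n = np.outer(q_n, N_n)

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -(_nb_loglik(y_t, mu_t, phi) + _nb_loglik(y_n, mu_n, phi))

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(np.exp(res.x))
    at_boundary = phi <= _PHI_LO * 1.01 or phi >= _PHI_HI * 0.99
    if at_boundary:
        logger.warning("dispersion estimate at search boundary: phi=%.3g", phi)
    return DispersionEstimate(
        phi=phi, bcv=float(np.sqrt(phi)), n_genes_used=n_used, at_boundary=at_boundary
    )


def single_sample_deg(
    counts: CountsMatrix, tumor_sample: str, phi: float, config: RunConfig
) -> DEGProfile:
    """Contrast one tumor sample against the pooled normals.

    logFC_g = log2((cpm_tumor + prior) / (mean normal cpm + prior));
    logCPM_g = log2(mean cpm across the tumor sample and all normals +
    prior). A two-sided NB tail test of the tumor count against its
    expectation under the pooled-normal rate (dispersion phi) is exported
    per gene but never used as a feature.
    """
    if counts.condition.get(tumor_sample) != TUMOR:
        raise ValueError(f"{tumor_sample!r} is not a tumor sample")
    normals = counts.normal_samples
    if not normals:
        raise ValueError("no normal samples available for the contrast")
    prior = config.logcpm_prior
    cpms = cpm_matrix(counts.counts)
    cpm_t = cpms[tumor_sample].to_numpy()
    cpm_n = cpms[normals].mean(axis=1).to_numpy()
    logfc = np.log2(cpm_t + prior) - np.log2(cpm_n + prior)
    logcpm = np.log2(cpms[[tumor_sample] + normals].mean(axis=1).to_numpy() + prior)

    libsize = counts.counts.sum(axis=0)
    q_n = counts.counts[normals].sum(axis=1).to_numpy(dtype=float) / float(
        libsize[normals].sum()
    )
    mu_t = q_n * float(libsize[tumor_sample])
    y_t = counts.counts[tumor_sample].to_numpy(dtype=float)
    r = 1.0 / max(phi, _PHI_LO)
    p = r / (r + np.maximum(mu_t, 1e-12))
    lower = nbinom.cdf(y_t, r, p)
    upper = nbinom.sf(y_t - 1, r, p)
    pval = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    pval = np.where(mu_t > 0, pval, np.where(y_t == 0, 1.0, 0.0))

    return DEGProfile(
        sample_id=tumor_sample,
        genes=list(counts.counts.index),
        logfc=logfc,
        logcpm=logcpm,
        p_value=pval,
        is_deg=np.abs(logfc) > config.tau,
    )


def all_sample_degs(
    counts: CountsMatrix, phi: float, config: RunConfig
) -> dict[str, DEGProfile]:
    return {
        s: single_sample_deg(counts, s, phi, config) for s in counts.tumor_samples
    }


def neigh_fc(
    gene: str,
    neighbors: set[str],
    logfc_map: dict[str, float],
    tau: float,
) -> tuple[float, float]:
    """Summed (and per-DEG-neighbor mean) logFC over DE neighbors.

    A neighbor contributes iff |logFC| > tau. Neighbors without expression
    data do not contribute.
    """
    contrib = [
        logfc_map[v] for v in neighbors if v in logfc_map and abs(logfc_map[v]) > tau
    ]
    if not contrib:
        return 0.0, 0.0
    total = float(sum(contrib))
    return total, total / len(contrib)


RNA_FEATURES = (
    "logFC",
    "logCPM",
    "is_deg",
    "degree",
    "closeness",
    "betweenness",
    "logFC_x_degree",
    "logFC_x_closeness",
    "logFC_x_betweenness",
    "neigh_FC",
    "neigh_normFC",
)


def assemble_rna_features(
    deg_profiles: dict[str, DEGProfile],
    node_stats: dict[str, NodeStats],
    altered_pairs: set[tuple[str, str]],
    config: RunConfig,
) -> pd.DataFrame:
    """One RNA feature row per altered (sample, gene) pair.

    Genes absent from the network get zero centralities and zero
    neighborhood features; pairs of samples without an expression profile
    are dropped with a warning.
    """
    rows = []
    dropped_samples: set[str] = set()
    lfc_maps = {s: p.logfc_map() for s, p in deg_profiles.items()}
    lcpm_maps = {
        s: dict(zip(p.genes, p.logcpm)) for s, p in deg_profiles.items()
    }
    for sample, gene in sorted(altered_pairs):
        prof = deg_profiles.get(sample)
        if prof is None:
            dropped_samples.add(sample)
            continue
        lfc_map = lfc_maps[sample]
        lfc = float(lfc_map.get(gene, 0.0))
        lcpm = float(lcpm_maps[sample].get(gene, 0.0))
        ns = node_stats.get(gene)
        if ns is None:
            deg = clo = bet = 0.0
            nfc = nnfc = 0.0
        else:
            deg, clo, bet = float(ns.degree), ns.closeness, ns.betweenness
            neigh = ns.neighbors_by_hop.get(config.hops, set())
            nfc, nnfc = neigh_fc(gene, neigh, lfc_map, config.tau)
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "logFC": lfc,
                "logCPM": lcpm,
                "is_deg": int(abs(lfc) > config.tau),
                "degree": deg,
                "closeness": clo,
                "betweenness": bet,
                "logFC_x_degree": lfc * deg,
                "logFC_x_closeness": lfc * clo,
                "logFC_x_betweenness": lfc * bet,
                "neigh_FC": nfc,
                "neigh_normFC": nnfc,
            }
        )
    if dropped_samples:
        logger.warning(
            "pairs dropped for samples without expression profiles: %s",
            sorted(dropped_samples),
        )
    return pd.DataFrame(rows, columns=["sample", "gene", *RNA_FEATURES])
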