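"""Synthetic multi-omic cohorts with planted TSG/OG signal.

The generator emulates the statistical structure the classifier exploits
in real tumors, without imitating any real cohort's marginals:

* a scale-free interaction network in which planted drivers are biased
  toward hubs;
* negative-binomial counts with log-normal gene baselines, per-sample
  library sizes, and a common dispersion (BCV^2); altered drivers shift
  expression multiplicatively (tumor suppressors down, oncogenes up) in a
  random subset of the samples carrying the alteration, and drag their
  network neighbors in the same direction, so neighborhood features carry
  signal tied to the true wiring;
* damaging impact scores for driver mutations vs benign scores elsewhere,
  with a configurable missing-score rate, consequence-type profiles per
  role, and planted onco-domain annotations;
* copy-number calls planted preferentially in drivers with sign matched
  to role, plus background alterations;
* an onco-miRNA expression block;
* driver/neutral resource lists consistent with the planted classes, with
  decoys (sub-threshold evidence, dual-role gene, unknown tag) that
  exercise the filtering rules.

Everything is deterministic given the seed.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MISSING, RunConfig
from .io import (
    CNVMatrix,
    CountsMatrix,
    DriverResources,
    EdgeList,
    MiRNAMatrix,
    MutationRecord,
    NORMAL,
    TUMOR,
    write_matrix,
)
from .pipeline import Cohort

TSG_TYPES = (("nonsense", 0.4), ("frameshift_del", 0.2), ("missense", 0.3), ("splice", 0.1))
OG_TYPES = (("missense", 0.8), ("inframe_del", 0.1), ("splice", 0.1))
BENIGN_TYPES = (("silent", 0.4), ("missense", 0.5), ("other", 0.1))

TSG_DOMAIN = "PF00870"
OG_DOMAIN = "PF00028"
DECOY_DOMAIN = "PF99999"


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 100
    n_normal: int = 20
    n_genes: int = 300
    n_tsg: int = 15
    n_og: int = 15
    n_neutral: int = 60
    true_bcv: float = 0.4
    planted_logfc: float = 2.0  # |log2 FC| of an active altered driver
    active_prob: float = 0.7  # P(expression effect | driver altered in sample)
    neighbor_logfc: float = 1.5  # |log2 FC| of a co-deregulated neighbor
    neighbor_prob: float = 0.7  # P(a neighbor joins the driver's program)
    background_de_rate: float = 0.25  # per-gene chance of a constitutive tumor program
    driver_score_range: tuple[float, float] = (0.7, 1.0)  # oriented damaging scores
    benign_score_range: tuple[float, float] = (0.0, 0.5)
    missing_score_rate: float = 0.15
    mutation_rate_driver: float = 0.35  # per tumor sample per planted driver
    mutation_rate_neutral: float = 0.15
    mutation_rate_background: float = 0.03
    cnv_rate_driver: float = 0.30
    cnv_rate_neutral: float = 0.08
    cnv_rate_background: float = 0.03
    hub_bias: float = 1.0  # driver sampling weight ~ degree**hub_bias
    mutation_driver_listed_prob: float = 0.8  # listed with evidence > threshold
    n_mirnas: int = 30
    n_onco_mirnas: int = 8
    cancer_type: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tsg + self.n_og + self.n_neutral > self.n_genes:
            raise ValueError("planted classes exceed the number of genes")
        if not 0 < self.n_normal < self.n_samples:
            raise ValueError("need at least one normal and one tumor sample")


@dataclass
class GroundTruth:
    """Planted classes and per-gene attributes, consistent with the files."""

    gene_class: dict[str, str]  # gene -> TSG | OG | NEUTRAL | NONE
    pair_class: dict[tuple[str, str], str]  # altered (sample, gene) -> class
    hub_flag: dict[str, bool]
    planted_domain: dict[str, str]  # gene -> domain accession or ""
    planted_logfc: dict[str, float] | None = None  # constitutive + own effect

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "gene": g, "planted_class": c}
            for (s, g), c in sorted(self.pair_class.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "planted_class"])


def default_run_config(synth: SynthConfig) -> RunConfig:
    """RunConfig matching the generator's planted encodings."""
    onco = tuple(f"mir{j:03d}" for j in range(synth.n_onco_mirnas))
    return RunConfig(
        seed=synth.seed,
        cancer_domains=(TSG_DOMAIN, OG_DOMAIN),
        onco_mirnas=onco,
    )


def _choice(rng: np.random.Generator, table: tuple[tuple[str, float], ...]) -> str:
    names = [t[0] for t in table]
    probs = np.array([t[1] for t in table])
    return str(rng.choice(names, p=probs / probs.sum()))


def _simulate_network(cfg: SynthConfig, rng: np.random.Generator, genes: list[str]):
    """Preferential-attachment edges, all above the retention cutoff,
    plus sub-threshold decoy edges that readers must filter out."""
    import networkx as nx

    g = nx.barabasi_albert_graph(cfg.n_genes, m=2, seed=int(rng.integers(2**31 - 1)))
    rows = []
    for a, b in sorted(g.edges()):
        rows.append(
            (
                genes[a],
                genes[b],
                int(rng.integers(701, 1001)),
                int(rng.integers(0, 1001)),
            )
        )
    # decoy edges below / at the cutoff
    for _ in range(cfg.n_genes // 10):
        a, b = rng.integers(0, cfg.n_genes, size=2)
        if a == b:
            continue
        rows.append((genes[a], genes[b], int(rng.integers(0, 700)), 700))
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "experimental_score", "database_score"]
    )
    degrees = dict(g.degree())
    return df, {genes[i]: degrees[i] for i in range(cfg.n_genes)}, {
        genes[a]: {genes[b] for b in g.neighbors(a)} for a in g.nodes
    }


def simulate_nb_counts(
    n_genes: int,
    n_tumor: int,
    n_normal: int,
    bcv: float,
    seed: int,
    logfc: np.ndarray | None = None,
    mean_count: float = 500.0,
) -> CountsMatrix:
    """Plain NB count matrix for parameter-recovery studies.

    ``logfc`` (per gene, log2 units) shifts tumor means multiplicatively;
    dispersion is bcv^2 (Poisson when bcv == 0). Library sizes are drawn
    Uniform(0.5e6, 2e6) and absorbed as offsets downstream.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"T{i:03d}" for i in range(n_tumor)] + [
        f"N{i:03d}" for i in range(n_normal)
    ]
    base = rng.lognormal(mean=np.log(mean_count), sigma=1.0, size=n_genes)
    q = base / base.sum()
    libsize = rng.uniform(0.5e6, 2.0e6, size=n_tumor + n_normal)
    fold = np.ones((n_genes, n_tumor + n_normal))
    if logfc is not None:
        fold[:, :n_tumor] = 2.0 ** np.asarray(logfc)[:, None]
    mu = np.outer(q, libsize) * fold
    mu /= mu.sum(axis=0) / libsize  # keep library sizes as drawn
    if bcv > 0:
        r = 1.0 / bcv**2
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    condition = {s: (TUMOR if s.startswith("T") else NORMAL) for s in samples}
    return CountsMatrix(df, condition)


def simulate_cohort(cfg: SynthConfig) -> tuple[Cohort, GroundTruth]:
    """Generate the six cohort inputs plus ground truth, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    n_tumor = cfg.n_samples - cfg.n_normal
    tumor = [f"S{i:03d}" for i in range(n_tumor)]
    normal = [f"N{i:03d}" for i in range(cfg.n_normal)]

    edge_df, degrees, adjacency = _simulate_network(cfg, rng, genes)

    # planted classes: drivers biased toward hubs
    deg_arr = np.array([degrees[g] for g in genes], dtype=float)
    w = deg_arr**cfg.hub_bias
    driver_idx = rng.choice(
        cfg.n_genes, size=cfg.n_tsg + cfg.n_og, replace=False, p=w / w.sum()
    )
    tsg_genes = [genes[i] for i in driver_idx[: cfg.n_tsg]]
    og_genes = [genes[i] for i in driver_idx[cfg.n_tsg :]]
    remaining = [g for g in genes if g not in set(tsg_genes) | set(og_genes)]
    neutral_genes = sorted(
        rng.choice(remaining, size=cfg.n_neutral, replace=False).tolist()
    )
    gene_class = {g: "NONE" for g in genes}
    gene_class.update({g: "TSG" for g in tsg_genes})
    gene_class.update({g: "OG" for g in og_genes})
    gene_class.update({g: "NEUTRAL" for g in neutral_genes})
    role_sign = {**{g: -1.0 for g in tsg_genes}, **{g: +1.0 for g in og_genes}}

    # alterations -----------------------------------------------------------
    mut_pairs: dict[tuple[str, str], None] = {}
    cnv = pd.DataFrame(0, index=genes, columns=tumor, dtype=int)
    for s in tumor:
        for g in genes:
            cls = gene_class[g]
            mut_rate = {
                "TSG": cfg.mutation_rate_driver,
                "OG": cfg.mutation_rate_driver,
                "NEUTRAL": cfg.mutation_rate_neutral,
                "NONE": cfg.mutation_rate_background,
            }[cls]
            cnv_rate = {
                "TSG": cfg.cnv_rate_driver,
                "OG": cfg.cnv_rate_driver,
                "NEUTRAL": cfg.cnv_rate_neutral,
                "NONE": cfg.cnv_rate_background,
            }[cls]
            if rng.random() < mut_rate:
                mut_pairs[(s, g)] = None
            if rng.random() < cnv_rate:
                mag = int(rng.choice([1, 2]))
                sign = role_sign.get(g, float(rng.choice([-1.0, 1.0])))
                cnv.loc[g, s] = int(sign * mag)

    altered = set(mut_pairs) | {
        (s, g) for g in genes for s in tumor if cnv.loc[g, s] != 0
    }

    # expression ------------------------------------------------------------
    # Constitutive tumor programs (identical in every tumor sample, so the
    # two-group mean model absorbs them and the common dispersion stays
    # clean): neighbors of planted drivers are dragged in the driver's
    # direction, and a background fraction of genes is deregulated with
    # random sign (confusable decoys). On top of that, the driver's own
    # effect is per-sample: present only when the gene is altered in the
    # sample and the alteration is expressed (active_prob).
    samples = tumor + normal
    base = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=cfg.n_genes)
    q = base / base.sum()
    libsize = rng.uniform(0.5e6, 2.0e6, size=len(samples))
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}

    gene_logfc = np.zeros(cfg.n_genes)
    for g in tsg_genes + og_genes:
        for nb in sorted(adjacency.get(g, ())):
            if rng.random() < cfg.neighbor_prob:
                gene_logfc[gidx[nb]] += role_sign[g] * cfg.neighbor_logfc
    bg = rng.random(cfg.n_genes) < cfg.background_de_rate
    bg_sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    gene_logfc += bg * bg_sign * cfg.planted_logfc

    log2fold = np.zeros((cfg.n_genes, len(samples)))
    log2fold[:, :n_tumor] += gene_logfc[:, None]
    active_pairs: set[tuple[str, str]] = set()
    for s in tumor:
        for g in tsg_genes + og_genes:
            if (s, g) in altered and rng.random() < cfg.active_prob:
                active_pairs.add((s, g))
                log2fold[gidx[g], sidx[s]] += role_sign[g] * cfg.planted_logfc

    mu = np.outer(q, libsize) * 2.0**log2fold
    if cfg.true_bcv > 0:
        r = 1.0 / cfg.true_bcv**2
        counts_arr = rng.negative_binomial(r, r / (r + mu))
    else:
        counts_arr = rng.poisson(mu)
    counts = CountsMatrix(
        pd.DataFrame(counts_arr, index=genes, columns=samples),
        {s: (TUMOR if s in set(tumor) else NORMAL) for s in samples},
    )

    # mutations -------------------------------------------------------------
    run_cfg = default_run_config(cfg)
    bases = np.array(list("ACGT"))
    records: list[MutationRecord] = []
    driver_rows = []
    for s, g in sorted(mut_pairs):
        cls = gene_class[g]
        if cls == "TSG":
            mtype = _choice(rng, TSG_TYPES)
        elif cls == "OG":
            mtype = _choice(rng, OG_TYPES)
        else:
            mtype = _choice(rng, BENIGN_TYPES)
        pos = int(rng.integers(1, 10_000))
        ref, alt = rng.choice(bases, size=2, replace=False)
        lo, hi = (
            cfg.driver_score_range if cls in ("TSG", "OG") else cfg.benign_score_range
        )
        oriented = float(rng.uniform(lo, hi))
        scores: dict = {}
        preds: dict = {}
        for tool in run_cfg.tools:
            noisy = float(np.clip(oriented + rng.normal(0, 0.05), 0.0, 1.0))
            if rng.random() < cfg.missing_score_rate:
                scores[tool] = MISSING
                preds[tool] = MISSING
                continue
            raw = noisy if run_cfg.tool_orientation[tool] else 1.0 - noisy
            scores[tool] = raw
            cats = run_cfg.tool_categories[tool]
            if len(cats) == 2:
                preds[tool] = cats[1] if noisy >= 0.5 else cats[0]
            else:
                preds[tool] = cats[2] if noisy >= 0.7 else cats[1] if noisy >= 0.45 else cats[0]
        if cls == "TSG" and rng.random() < 0.5:
            domains = frozenset({TSG_DOMAIN})
        elif cls == "OG" and rng.random() < 0.5:
            domains = frozenset({OG_DOMAIN})
        elif rng.random() < 0.2:
            domains = frozenset({DECOY_DOMAIN})
        else:
            domains = frozenset()
        records.append(
            MutationRecord(
                sample_id=s,
                gene=g,
                chrom="chr1",
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                mutation_type=mtype,
                tool_scores=scores,
                tool_preds=preds,
                domains=domains,
            )
        )
        if cls in ("TSG", "OG"):
            if rng.random() < cfg.mutation_driver_listed_prob:
                evidence = float(rng.uniform(16, 100))
            else:
                evidence = float(rng.uniform(0, 15))
            driver_rows.append(
                {
                    "gene": g,
                    "pos": pos,
                    "ref": str(ref),
                    "alt": str(alt),
                    "label": cls,
                    "evidence_score": evidence,
                }
            )

    # miRNA -----------------------------------------------------------------
    mirnas = [f"mir{j:03d}" for j in range(cfg.n_mirnas)]
    onco = tuple(mirnas[: cfg.n_onco_mirnas])
    mir_base = rng.lognormal(mean=3.0, sigma=0.5, size=(cfg.n_mirnas, n_tumor))
    mir_base[: cfg.n_onco_mirnas] *= 1.5  # onco-miRNAs run hotter in tumors
    mirna = MiRNAMatrix(
        pd.DataFrame(np.round(mir_base, 3), index=mirnas, columns=tumor), onco
    )

    # driver resources ------------------------------------------------------
    gene_rows = []
    tag_pool = {"TSG": ("tsg", "possible tsg"), "OG": ("oncogene", "possible oncogene")}
    for g in sorted(tsg_genes):
        tag = tag_pool["TSG"][int(rng.integers(0, 2))]
        gene_rows.append({"gene": g, "tag": tag, "cancer_type": "PAN"})
        gene_rows.append({"gene": g, "tag": tag, "cancer_type": cfg.cancer_type})
    for g in sorted(og_genes):
        tag = tag_pool["OG"][int(rng.integers(0, 2))]
        gene_rows.append({"gene": g, "tag": tag, "cancer_type": "PAN"})
        gene_rows.append({"gene": g, "tag": tag, "cancer_type": cfg.cancer_type})
    # decoys: one dual-role gene and one unknown tag (ignored loudly)
    decoy_pool = [g for g in genes if gene_class[g] == "NONE"]
    dual = decoy_pool[0]
    gene_rows.append({"gene": dual, "tag": "tsg", "cancer_type": "PAN"})
    gene_rows.append({"gene": dual, "tag": "oncogene", "cancer_type": "PAN"})
    gene_rows.append({"gene": decoy_pool[1], "tag": "fusion", "cancer_type": "PAN"})

    resources = DriverResources(
        mutation_drivers=pd.DataFrame(
            driver_rows,
            columns=["gene", "pos", "ref", "alt", "label", "evidence_score"],
        ),
        gene_drivers=pd.DataFrame(gene_rows, columns=["gene", "tag", "cancer_type"]),
        neutral_genes=set(neutral_genes),
    )

    cohort = Cohort(
        mutations=records,
        counts=counts,
        cnv=CNVMatrix(cnv),
        mirna=mirna,
        edges=EdgeList(
            edge_df[
                (np.maximum(edge_df["experimental_score"], edge_df["database_score"]) > 700)
                & (edge_df["gene_a"] != edge_df["gene_b"])
            ].reset_index(drop=True)
        ),
        resources=resources,
        raw_edge_table=edge_df,
    )

    pair_class = {}
    for s, g in sorted(altered):
        cls = gene_class[g]
        pair_class[(s, g)] = cls if cls != "NONE" else "UNLABELED"
    med_deg = float(np.median(deg_arr))
    truth = GroundTruth(
        gene_class=gene_class,
        pair_class=pair_class,
        hub_flag={g: degrees[g] > med_deg for g in genes},
        planted_domain={
            **{g: TSG_DOMAIN for g in tsg_genes},
            **{g: OG_DOMAIN for g in og_genes},
        },
        planted_logfc={
            g: float(
                gene_logfc[gidx[g]]
                + role_sign.get(g, 0.0) * cfg.planted_logfc * (gene_class[g] in ("TSG", "OG"))
            )
            for g in genes
        },
    )
    return cohort, truth


def _mutations_frame(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    rows = []
    for m in cohort.mutations:
        row = {
            "sample": m.sample_id,
            "gene": m.gene,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "type": m.mutation_type,
        }
        for tool in config.tools:
            sc = m.tool_scores.get(tool, MISSING)
            pr = m.tool_preds.get(tool, MISSING)
            row[f"{tool}_score"] = "." if sc is MISSING else f"{sc:.6g}"
            row[f"{tool}_pred"] = "." if pr is MISSING else pr
        row["domains"] = config.domain_delimiter.join(sorted(m.domains)) or "."
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: Cohort,
    truth: GroundTruth | None,
    directory: str | Path,
    config: RunConfig,
) -> None:
    """Write the cohort in the layout :func:`pipeline.load_cohort` reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _mutations_frame(cohort, config).to_csv(d / "mutations.tsv", sep="\t", index=False)
    write_matrix(cohort.counts.counts, d / "counts.tsv", "gene")
    pd.DataFrame(
        sorted(cohort.counts.condition.items()), columns=["sample", "condition"]
    ).to_csv(d / "conditions.tsv", sep="\t", index=False)
    write_matrix(cohort.cnv.scores, d / "cnv.tsv", "gene")
    write_matrix(cohort.mirna.expression, d / "mirna.tsv", "mirna")
    pd.DataFrame({"mirna": list(cohort.mirna.onco_mirnas)}).to_csv(
        d / "onco_mirnas.tsv", sep="\t", index=False
    )
    edge_table = getattr(cohort, "raw_edge_table", cohort.edges.edges)
    edge_table.to_csv(d / "network.tsv", sep="\t", index=False)
    md = cohort.resources.mutation_drivers.copy()
    md["evidence_score"] = [
        "." if v is MISSING else f"{v:.6g}" for v in md["evidence_score"]
    ]
    md.to_csv(d / "driver_mutations.tsv", sep="\t", index=False)
    cohort.resources.gene_drivers.to_csv(d / "driver_genes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": sorted(cohort.resources.neutral_genes)}).to_csv(
        d / "neutral_genes.tsv", sep="\t", index=False
    )
    if truth is not None:
        truth.to_frame().to_csv(d / "ground_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hand-checkable worked example

_TOY_COUNTS = """gene\tS1\tS2\tS3\tN1\tN2
G1\t25\t100\t100\t100\t100
G2\t400\t100\t100\t100\t100
G3\t175\t200\t200\t200\t200
G4\t200\t100\t200\t200\t200
G5\t100\t300\t200\t200\t200
G6\t100\t200\t200\t200\t200
"""

_TOY_MUTATIONS = [
    # sample, gene, pos, ref, alt, type, oriented score or None (=MISSING), domains
    ("S1", "G1", 100, "A", "T", "nonsense", 0.9, "PF00870"),
    ("S1", "G1", 120, "C", "T", "missense", 0.8, ""),
    ("S2", "G1", 130, "G", "A", "missense", 0.85, "PF00870"),
    ("S1", "G2", 200, "G", "A", "missense", 0.95, "PF00028"),
    ("S2", "G3", 300, "T", "C", "silent", 0.1, ""),
    ("S3", "G5", 500, "A", "C", "missense", 0.9, ""),
    ("S3", "G5", 510, "T", "G", "missense", 0.88, ""),
    ("S2", "G4", 400, "A", "G", "missense", None, ""),
]

_TOY_DRIVER_MUTATIONS = [
    # gene, pos, ref, alt, label, evidence
    ("G1", 100, "A", "T", "TSG", 20.0),
    ("G1", 150, "C", "G", "TSG", 15.0),  # dropped: evidence not > 15
    ("G2", 200, "G", "A", "OG", 30.0),
    ("G5", 500, "A", "C", "TSG", 18.0),
    ("G5", 510, "T", "G", "OG", 22.0),  # conflict with the row above in S3
]

_TOY_GENE_DRIVERS = [
    ("G1", "tsg", "PAN"),
    ("G2", "oncogene", "PAN"),
    ("G5", "possible tsg", "PAN"),
    ("G5", "possible oncogene", "PAN"),  # dual role: excluded
    ("G6", "tsg", "PAN"),
    ("G1", "possible tsg", "TOY"),
    ("G2", "possible oncogene", "TOY"),
]

_TOY_EDGES = [
    # gene_a, gene_b, experimental, database
    ("G1", "G2", 800, 0),
    ("G2", "G3", 750, 0),
    ("G3", "G4", 0, 900),
    ("G4", "G5", 999, 999),
    ("G1", "G6", 700, 700),  # boundary: dropped (strict >)
    ("G6", "G6", 900, 900),  # self-loop: dropped
]


def toy_worked_example() -> tuple[Cohort, RunConfig]:
    """Six genes, three tumor samples, every labeling edge case on display.

    G1 is a listed tumor suppressor with one exact driver mutation in S1,
    G2 an oncogene, G3 a neutral gene, G4 unlabeled with a missing SIFT
    score, G5 a dual-role gene (excluded at the gene level, conflicting at
    the mutation level), and G6 an off-network gene altered only by a deep
    deletion in S3.
    """
    config = RunConfig(cancer_domains=("PF00870", "PF00028"), onco_mirnas=("mirA",))
    counts_df = pd.read_csv(_io.StringIO(_TOY_COUNTS), sep="\t").set_index("gene")
    condition = {"S1": TUMOR, "S2": TUMOR, "S3": TUMOR, "N1": NORMAL, "N2": NORMAL}

    records = []
    for s, g, pos, ref, alt, mtype, oriented, dom in _TOY_MUTATIONS:
        scores: dict = {}
        preds: dict = {}
        for tool in config.tools:
            if oriented is None:
                scores[tool] = MISSING
                preds[tool] = MISSING
                continue
            raw = oriented if config.tool_orientation[tool] else 1.0 - oriented
            scores[tool] = raw
            cats = config.tool_categories[tool]
            if len(cats) == 2:
                preds[tool] = cats[1] if oriented >= 0.5 else cats[0]
            else:
                preds[tool] = cats[2] if oriented >= 0.7 else cats[1] if oriented >= 0.45 else cats[0]
        records.append(
            MutationRecord(
                sample_id=s,
                gene=g,
                chrom="chr1",
                pos=pos,
                ref=ref,
                alt=alt,
                mutation_type=mtype,
                tool_scores=scores,
                tool_preds=preds,
                domains=frozenset(d for d in dom.split(";") if d),
            )
        )

    cnv = pd.DataFrame(0, index=list(counts_df.index), columns=["S1", "S2", "S3"])
    cnv.loc["G6", "S3"] = -2
    cnv.loc["G1", "S1"] = -1

    mirna = MiRNAMatrix(
        pd.DataFrame(
            [[5.0, 6.0, 7.0], [1.0, 1.0, 1.0]],
            index=["mirA", "mirB"],
            columns=["S1", "S2", "S3"],
        ),
        ("mirA",),
    )

    edge_df = pd.DataFrame(
        _TOY_EDGES, columns=["gene_a", "gene_b", "experimental_score", "database_score"]
    )
    kept = edge_df[
        (np.maximum(edge_df["experimental_score"], edge_df["database_score"]) > 700)
        & (edge_df["gene_a"] != edge_df["gene_b"])
    ].reset_index(drop=True)

    resources = DriverResources(
        mutation_drivers=pd.DataFrame(
            _TOY_DRIVER_MUTATIONS,
            columns=["gene", "pos", "ref", "alt", "label", "evidence_score"],
        ),
        gene_drivers=pd.DataFrame(
            _TOY_GENE_DRIVERS, columns=["gene", "tag", "cancer_type"]
        ),
        neutral_genes={"G3"},
    )

    cohort = Cohort(
        mutations=records,
        counts=CountsMatrix(counts_df, condition),
        cnv=CNVMatrix(cnv),
        mirna=mirna,
        edges=EdgeList(kept),
        resources=resources,
        raw_edge_table=edge_df,
    )
    return cohort, config
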