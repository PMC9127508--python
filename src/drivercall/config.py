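"""Run-level configuration, shared vocabularies, and the MISSING sentinel.

A single :class:`RunConfig` instance carries every threshold and encoding
choice a pipeline run depends on, so that two runs with equal configs and
seeds are reproducible down to the byte.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any


class _Missing:
    """Typed sentinel for absent tool scores/predictions.

    Distinct from 0.0 and from NaN: a missing SIFT score means the tool
    could not evaluate the mutation, not that the mutation is benign.
    """

    _instance = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: Fixed vocabulary of mutation consequence types; anything else maps to "other".
MUTATION_TYPES: tuple[str, ...] = (
    "missense",
    "nonsense",
    "frameshift_ins",
    "frameshift_del",
    "inframe_ins",
    "inframe_del",
    "splice",
    "silent",
    "other",
)

#: Most- to least-severe consequence order, used only to break ties when
#: choosing the representative mutation of a (sample, gene) pair.
DEFAULT_SEVERITY_ORDER: tuple[str, ...] = (
    "nonsense",
    "frameshift_del",
    "frameshift_ins",
    "splice",
    "inframe_del",
    "inframe_ins",
    "missense",
    "silent",
    "other",
)

LABELS = ("NEUTRAL", "DRIVER", "TSG", "OG", "UNLABELED")

STRATEGIES = (
    "MUTATION_EXACT_BINARY",
    "MUTATION_EXACT_TSG_OG",
    "GENE_PAN",
    "GENE_CANCER_SPECIFIC",
)


@dataclass
class RunConfig:
    """All tunable thresholds and encodings for one pipeline run.

    Attributes
    ----------
    string_score_cutoff:
        Interaction edges are kept iff max(experimental, database) score is
        strictly above this value (STRING-style 0-1000 scale).
    evidence_threshold:
        Mutation-level driver records are kept iff their evidence score is
        strictly above this value.
    hops:
        Neighborhood radius (in hops) for network neighborhood features.
    tau:
        |log2 fold change| threshold defining a differentially expressed
        neighbor; 1.0 corresponds to a two-fold change.
    logcpm_prior:
        Prior count added before log2 in CPM/fold-change computations.
    split_ratio:
        Fraction of samples assigned to the training side of the split.
    tools:
        Ordered tool names; each tool contributes a ``<tool>_score`` and a
        ``<tool>_pred`` column in the mutation table.
    tool_categories:
        Per-tool ordered category list, benign first, most damaging last.
        Ordinal encoding maps the k-th category (1-based) to k, MISSING to 0.
    tool_orientation:
        Per-tool flag: True if larger raw scores mean more damaging. Tools
        with False (e.g. SIFT) are re-oriented as 1 - score before
        aggregation so that "max" always keeps the most damaging evidence.
    severity_order:
        Tie-break order over mutation types (most severe first).
    cancer_domains:
        Ordered Pfam accessions used as binary onco-domain features for the
        run's cancer type.
    onco_mirnas:
        Ordered miRNA names whose sample-level expression enters the
        multi-omic block (the cancer-associated subset).
    mutation_drivers_precurated:
        If True, mutation-level driver rows with a MISSING evidence score
        are retained (list already curated); otherwise they are dropped.
    """

    string_score_cutoff: int = 700
    evidence_threshold: float = 15.0
    hops: int = 1
    tau: float = 1.0
    logcpm_prior: float = 0.5
    split_ratio: float = 0.70
    seed: int = 0
    cv_folds: int = 5
    feature_set: str = "all"

    tools: tuple[str, ...] = ("SIFT", "PolyPhen2", "FATHMM")
    tool_categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "SIFT": ("N", "D"),
            "PolyPhen2": ("B", "P", "D"),
            "FATHMM": ("N", "D"),
        }
    )
    tool_orientation: dict[str, bool] = field(
        default_factory=lambda: {"SIFT": False, "PolyPhen2": True, "FATHMM": True}
    )
    severity_order: tuple[str, ...] = DEFAULT_SEVERITY_ORDER
    domain_delimiter: str = ";"
    cancer_domains: tuple[str, ...] = ("PF00870", "PF00028")
    onco_mirnas: tuple[str, ...] = ()
    mutation_drivers_precurated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.hops < 1:
            raise ValueError(f"hops must be >= 1, got {self.hops}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.feature_set not in ("all", "small"):
            raise ValueError(f"feature_set must be 'all' or 'small', got {self.feature_set!r}")
        for tool in self.tools:
            if tool not in self.tool_categories:
                raise ValueError(f"tool {tool!r} has no declared category order")
            if tool not in self.tool_orientation:
                raise ValueError(f"tool {tool!r} has no declared score orientation")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("tools", "severity_order", "cancer_domains", "onco_mirnas"):
            d[key] = list(d[key])
        d["tool_categories"] = {k: list(v) for k, v in d["tool_categories"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key in ("tools", "severity_order", "cancer_domains", "onco_mirnas"):
            if key in d:
                d[key] = tuple(d[key])
        if "tool_categories" in d:
            d["tool_categories"] = {k: tuple(v) for k, v in d["tool_categories"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
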