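"""Per-drug evidence aggregation and headline summary statistics.

Each screened drug gets one record combining the pool-competition hits, the
robot-plate hits at their SD evidence level, indirect-effect genes (expert
curation, never inferred automatically), liquid-culture verification status,
competitor protection, and the Lipinski rule-of-five flag. The packaged
fixture transcribes the study's 26-drug summary table; gene symbols are
normalized to uppercase gene names while the raw cell text is kept
alongside (the printed table mixes e.g. "nrt1" and "nrt1Δ").
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._exceptions import ConfigError, InputError, IntegrityError

#: SHA-256 of the packaged 26-drug fixture; guards accidental edits.
TABLE1_SHA256 = "5a1546b743e4b7b4e70cc0f45e508d82cec05d5c1160cf8c2232490faac92d9f"

DEFAULT_EVIDENCE_SD = 3.0

FIXTURE_COLUMNS = [
    "drug", "pool_hits", "robot_conc_uM", "robot_hits", "indirect_hits",
    "verification", "verified_genes", "competitor_protects", "lipinski_pass",
    "raw_pool", "raw_robot", "raw_indirect",
]


@dataclass(frozen=True)
class GeneEvidence:
    """A gene hit with the SD threshold at which it was called (3, 2.5 or 2)."""

    gene: str
    sd: float = DEFAULT_EVIDENCE_SD

    def encode(self) -> str:
        return self.gene if self.sd == DEFAULT_EVIDENCE_SD else f"{self.gene}@{self.sd:g}"

    @classmethod
    def decode(cls, token: str) -> "GeneEvidence":
        if "@" in token:
            gene, _, sd = token.partition("@")
            return cls(gene, float(sd))
        return cls(token)


@dataclass
class DrugRecord:
    """One row of the per-drug evidence summary."""

    drug: str
    pool_hits: list[str] = field(default_factory=list)
    robot_conc_uM: float = float("nan")
    robot_hits: list[GeneEvidence] = field(default_factory=list)
    indirect_hits: list[GeneEvidence] = field(default_factory=list)
    verification: str = "not_tested"  # confirmed | partial | not_tested | solid_only
    verified_genes: list[str] = field(default_factory=list)
    competitor_protects: str = "not_tested"  # pass | not_tested
    lipinski_pass: bool = False
    raw: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        robot = {e.gene for e in self.robot_hits}
        indirect = {e.gene for e in self.indirect_hits}
        if robot & indirect:
            raise InputError(
                f"{self.drug}: genes {sorted(robot & indirect)} appear as both "
                "direct and indirect hits"
            )

    @property
    def direct_genes(self) -> set[str]:
        return set(self.pool_hits) | {e.gene for e in self.robot_hits}


@dataclass(frozen=True)
class SummaryStats:
    """Headline counts over a set of drug records."""

    n_drugs: int
    n_with_direct_hit: int
    n_lipinski_pass: int
    categories: dict[str, int]  # single_carrier | multiple | indirect_only | none


def _split(cell: str) -> list[str]:
    cell = (cell or "").strip()
    if not cell or cell == "None":
        return []
    return [tok for tok in cell.split(";") if tok]


def _records_from_frame(frame: pd.DataFrame) -> list[DrugRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DrugRecord(
                drug=row.drug,
                pool_hits=_split(row.pool_hits),
                robot_conc_uM=float(row.robot_conc_uM),
                robot_hits=[GeneEvidence.decode(t) for t in _split(row.robot_hits)],
                indirect_hits=[GeneEvidence.decode(t) for t in _split(row.indirect_hits)],
                verification=row.verification,
                verified_genes=_split(row.verified_genes),
                competitor_protects=row.competitor_protects,
                lipinski_pass=row.lipinski_pass == "pass",
                raw={
                    "pool": row.raw_pool,
                    "robot": row.raw_robot,
                    "indirect": row.raw_indirect,
                },
            )
        )
    return records


def records_to_frame(records: list[DrugRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "drug": r.drug,
                "pool_hits": ";".join(r.pool_hits),
                "robot_conc_uM": f"{r.robot_conc_uM:g}",
                "robot_hits": ";".join(e.encode() for e in r.robot_hits),
                "indirect_hits": ";".join(e.encode() for e in r.indirect_hits),
                "verification": r.verification,
                "verified_genes": ";".join(r.verified_genes),
                "competitor_protects": r.competitor_protects,
                "lipinski_pass": "pass" if r.lipinski_pass else "fail",
                "raw_pool": r.raw.get("pool", ""),
                "raw_robot": r.raw.get("robot", ""),
                "raw_indirect": r.raw.get("indirect", ""),
            }
        )
    return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)


def load_records(path: str | Path) -> list[DrugRecord]:
    """Load drug records from a TSV in the fixture column layout."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(FIXTURE_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"record table missing columns: {sorted(missing)}")
    return _records_from_frame(frame)


def load_table1_fixture(verify_checksum: bool = True) -> list[DrugRecord]:
    """The packaged 26-drug evidence summary, checksum-verified."""
    ref = resources.files("carrierscreen.data") / "table1.tsv"
    with resources.as_file(ref) as path:
        if verify_checksum:
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            if digest != TABLE1_SHA256:
                raise IntegrityError(
                    f"table1 fixture checksum mismatch: {digest} != {TABLE1_SHA256}"
                )
        return load_records(path)


def has_direct_hit(record: DrugRecord) -> bool:
    """True iff a pool or robot hit names a carrier (indirect hits don't count)."""
    return bool(record.direct_genes)


def categorize(record: DrugRecord) -> str:
    """none | indirect_only | single_carrier | multiple, by distinct direct genes."""
    n_direct = len(record.direct_genes)
    if n_direct == 0:
        return "indirect_only" if record.indirect_hits else "none"
    return "single_carrier" if n_direct == 1 else "multiple"


def summarize(records: list[DrugRecord]) -> SummaryStats:
    """Headline counts: drugs, drugs with an identified carrier, Lipinski passes."""
    categories = {"single_carrier": 0, "multiple": 0, "indirect_only": 0, "none": 0}
    for record in records:
        categories[categorize(record)] += 1
    return SummaryStats(
        n_drugs=len(records),
        n_with_direct_hit=sum(has_direct_hit(r) for r in records),
        n_lipinski_pass=sum(r.lipinski_pass for r in records),
        categories=categories,
    )


def build_summary(
    screens: list[dict],
    annotations: pd.DataFrame | None = None,
    classify_indirect: bool = False,
) -> list[DrugRecord]:
    """Assemble drug records from fresh screen outputs.

    Each entry of ``screens`` describes one drug::

        {"drug": str, "robot_conc_uM": float,
         "hit_calls": DataFrame from hits.call_hits (or None),
         "enrichment": DataFrame from pool.call_enrichment (or None),
         "gene_of": mapping strain_id -> gene name,
         "verification": str, "competitor_protects": str, "lipinski_pass": bool}

    Direct vs indirect classification of robot hits follows the supplied
    ``annotations`` table (columns ``gene``, ``classification`` with value
    ``indirect`` for genes acting on the drug's target rather than its
    import) — it is expert curation and is never inferred automatically.
    """
    if classify_indirect and annotations is None:
        raise ConfigError("indirect classification requested but no annotation table supplied")
    indirect_genes: set[str] = set()
    if annotations is not None:
        sel = annotations["classification"] == "indirect"
        indirect_genes = set(annotations.loc[sel, "gene"])
    records = []
    for screen in screens:
        gene_of = screen.get("gene_of", {})
        robot_hits, indirect_hits = [], []
        calls = screen.get("hit_calls")
        if calls is not None:
            mask = calls["call"] == "resistant"
            if "is_wildtype" in calls.columns:
                mask &= ~calls["is_wildtype"]
            resistant = calls[mask]
            for row in resistant.itertuples(index=False):
                gene = gene_of.get(row.strain_id, str(row.strain_id).rstrip("Δ").upper())
                evidence = GeneEvidence(gene, float(row.resistant_threshold_sd))
                if gene in indirect_genes:
                    indirect_hits.append(evidence)
                else:
                    robot_hits.append(evidence)
        pool_hits = []
        enrichment = screen.get("enrichment")
        if enrichment is not None:
            for row in enrichment[enrichment["enriched"]].itertuples(index=False):
                pool_hits.append(
                    gene_of.get(row.strain_id, str(row.strain_id).rstrip("Δ").upper())
                )
        records.append(
            DrugRecord(
                drug=screen["drug"],
                pool_hits=sorted(set(pool_hits)),
                robot_conc_uM=float(screen.get("robot_conc_uM", float("nan"))),
                robot_hits=robot_hits,
                indirect_hits=indirect_hits,
                verification=screen.get("verification", "not_tested"),
                competitor_protects=screen.get("competitor_protects", "not_tested"),
                lipinski_pass=bool(screen.get("lipinski_pass", False)),
            )
        )
    return records
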