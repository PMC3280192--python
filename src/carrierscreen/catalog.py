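"""Strain catalogs and robot plate layouts.

The screen works with the set of *S. cerevisiae* strains each deleted for one
plasma-membrane transporter gene, plus a wild-type (WT) control (an *HO*-locus
deletion with no growth phenotype). Strains are arrayed on a 384-well
(16 x 24) master plate — every border well WT to buffer edge effects, every
transporter strain in duplicate in the interior — and the master is spotted
twice onto agar to give a 768-spot (24 x 32) test plate with each mutant in
quadruplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._exceptions import CapacityError, ShapeError

MASTER_ROWS, MASTER_COLS = 16, 24
TEST_ROWS, TEST_COLS = 24, 32

WILDTYPE_ID = "WT"


@dataclass(frozen=True)
class StrainCatalog:
    """The strains entering a screen.

    ``frame`` has columns ``strain_id``, ``gene``, ``category`` where
    category is ``transporter_mutant`` or ``wildtype_control``. Strain ids
    are unique and exactly one entry is the wild-type control.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.frame["strain_id"]
        if ids.duplicated().any():
            raise ValueError("strain_ids must be unique")
        n_wt = (self.frame["category"] == "wildtype_control").sum()
        if n_wt != 1:
            raise ValueError(f"expected exactly one wildtype_control, got {n_wt}")

    @property
    def wildtype_id(self) -> str:
        row = self.frame[self.frame["category"] == "wildtype_control"]
        return str(row["strain_id"].iloc[0])

    @property
    def transporter_ids(self) -> list[str]:
        sel = self.frame["category"] == "transporter_mutant"
        return list(self.frame.loc[sel, "strain_id"])

    @property
    def n_transporters(self) -> int:
        return len(self.transporter_ids)

    def gene_of(self, strain_id: str) -> str:
        match = self.frame.loc[self.frame["strain_id"] == strain_id, "gene"]
        if match.empty:
            raise KeyError(strain_id)
        return str(match.iloc[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainCatalog":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def from_genes(cls, genes: list[str]) -> "StrainCatalog":
        """Build a catalog of deletion strains from gene names plus the WT."""
        rows = [{"strain_id": WILDTYPE_ID, "gene": "YDL227C", "category": "wildtype_control"}]
        rows += [
            {"strain_id": f"{g.lower()}Δ", "gene": g.upper(), "category": "transporter_mutant"}
            for g in genes
        ]
        return cls(pd.DataFrame(rows))


def default_catalog() -> StrainCatalog:
    """The packaged catalog: 111 plasma-membrane transporter deletants + WT."""
    ref = resources.files("carrierscreen.data") / "transporter_catalog.tsv"
    with resources.as_file(ref) as path:
        return StrainCatalog.from_tsv(path)


@dataclass(frozen=True)
class PlateLayout:
    """A grid of spot/well positions annotated with strain identity.

    ``frame`` has one row per position with columns ``row``, ``col``
    (0-based), ``strain_id``, ``replicate_index`` (1-based per transporter
    strain; 0 for WT buffer copies), and ``is_edge``.
    """

    n_rows: int
    n_cols: int
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.frame) != self.n_rows * self.n_cols:
            raise ShapeError(
                f"layout has {len(self.frame)} entries for a "
                f"{self.n_rows}x{self.n_cols} grid"
            )

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    def positions_of(self, strain_id: str) -> pd.DataFrame:
        return self.frame[self.frame["strain_id"] == strain_id]

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_table

        write_table(self.frame, path, {"n_rows": self.n_rows, "n_cols": self.n_cols})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlateLayout":
        from .io import read_metadata, read_table

        frame = read_table(path)
        meta = read_metadata(path)
        n_rows = int(meta.get("n_rows", frame["row"].max() + 1))
        n_cols = int(meta.get("n_cols", frame["col"].max() + 1))
        return cls(n_rows, n_cols, frame)


def _is_edge(row: int, col: int, n_rows: int, n_cols: int) -> bool:
    return row in (0, n_rows - 1) or col in (0, n_cols - 1)


def build_master_layout(catalog: StrainCatalog) -> PlateLayout:
    """Array the catalog on a 16 x 24 master plate.

    Every border well carries the WT control; each transporter strain
    occupies exactly two adjacent interior wells (row-major fill); interior
    wells left over are filled with additional WT copies, never left empty.
    """
    strains = catalog.transporter_ids
    if not strains:
        raise CapacityError("catalog holds no transporter strains")
    interior = [
        (r, c)
        for r in range(1, MASTER_ROWS - 1)
        for c in range(1, MASTER_COLS - 1)
    ]
    if 2 * len(strains) > len(interior):
        raise CapacityError(
            f"{len(strains)} strains need {2 * len(strains)} interior wells; "
            f"the {MASTER_ROWS}x{MASTER_COLS} master has only {len(interior)}"
        )
    wt = catalog.wildtype_id
    assignment: dict[tuple[int, int], tuple[str, int]] = {}
    for i, strain in enumerate(strains):
        for rep in (1, 2):
            assignment[interior[2 * i + rep - 1]] = (strain, rep)
    rows = []
    for r in range(MASTER_ROWS):
        for c in range(MASTER_COLS):
            strain, rep = assignment.get((r, c), (wt, 0))
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "strain_id": strain,
                    "replicate_index": rep,
                    "is_edge": _is_edge(r, c, MASTER_ROWS, MASTER_COLS),
                }
            )
    return PlateLayout(MASTER_ROWS, MASTER_COLS, pd.DataFrame(rows))


def build_test_layout(master: PlateLayout) -> PlateLayout:
    """Expand a 384-well master into the 768-spot (24 x 32) test plate.

    The robot's two spotting passes form two column-interleaved copies of
    the master inside the test grid: master well (r, c) maps to test
    positions (row=c, col=2r) and (row=c, col=2r+1). Quadruplicates are the
    union of a strain's two master wells and the two passes; the WT border
    of the master becomes the full border of the test plate.
    """
    if (master.n_rows, master.n_cols) != (MASTER_ROWS, MASTER_COLS):
        raise ShapeError(
            f"master must be {MASTER_ROWS}x{MASTER_COLS}, "
            f"got {master.n_rows}x{master.n_cols}"
        )
    rows = []
    for rec in master.frame.itertuples(index=False):
        for pass_index in (0, 1):
            trow, tcol = rec.col, 2 * rec.row + pass_index
            rep = 0 if rec.replicate_index == 0 else 2 * (rec.replicate_index - 1) + pass_index + 1
            rows.append(
                {
                    "row": trow,
                    "col": tcol,
                    "strain_id": rec.strain_id,
                    "replicate_index": rep,
                    "is_edge": _is_edge(trow, tcol, TEST_ROWS, TEST_COLS),
                }
            )
    frame = pd.DataFrame(rows).sort_values(["row", "col"]).reset_index(drop=True)
    return PlateLayout(TEST_ROWS, TEST_COLS, frame)
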