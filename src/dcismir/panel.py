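"""miRNA panels: ordered sets of (miRNA, direction, provenance).

Direction is the sign of the association with the Oncotype DX DCIS score
(or age): "down" means expression falls as the risk score rises. Provenance
records which screen nominated the miRNA ("score", "age" or "both").

Two panels ship with the package: ``qpcr5`` — the five qPCR-validated,
uniformly downregulated miRNAs behind the composite score — and ``ngs17``,
the seventeen sequencing-screen hits with their signed directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PanelMember", "MiRNAPanel", "load_builtin_panel", "BUILTIN_PANELS"]

DIRECTIONS = ("up", "down")
PROVENANCES = ("score", "age", "both")
BUILTIN_PANELS = {"qpcr5": "panel_qpcr5.csv", "ngs17": "panel_ngs17.csv"}


@dataclass(frozen=True)
class PanelMember:
    mirna_id: str
    direction: str
    provenance: str = "score"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @property
    def sign(self) -> int:
        """Contribution sign on the expression scale (+1 up, -1 down)."""
        return 1 if self.direction == "up" else -1


class MiRNAPanel:
    def __init__(self, members: list[PanelMember]):
        ids = [m.mirna_id for m in members]
        if len(set(ids)) != len(ids):
            raise ValueError("panel mirna_ids must be unique")
        self.members = list(members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, mirna_id: str) -> bool:
        return any(m.mirna_id == mirna_id for m in self.members)

    @property
    def mirna_ids(self) -> list[str]:
        return [m.mirna_id for m in self.members]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": [m.mirna_id for m in self.members],
                "direction": [m.direction for m in self.members],
                "provenance": [m.provenance for m in self.members],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MiRNAPanel":
        required = {"mirna_id", "direction"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel table needs columns {sorted(required)}")
        members = [
            PanelMember(
                str(row["mirna_id"]),
                str(row["direction"]),
                str(row.get("provenance", "score")),
            )
            for _, row in df.iterrows()
        ]
        return cls(members)

    @classmethod
    def from_csv(cls, path) -> "MiRNAPanel":
        return cls.from_dataframe(pd.read_csv(path))


def load_builtin_panel(name: str) -> MiRNAPanel:
    """Load a shipped panel by short name ("qpcr5" or "ngs17")."""
    if name not in BUILTIN_PANELS:
        raise KeyError(f"unknown panel {name!r}; choose from {sorted(BUILTIN_PANELS)}")
    with resources.as_file(
        resources.files("dcismir.data").joinpath(BUILTIN_PANELS[name])
    ) as p:
        return MiRNAPanel.from_csv(p)
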