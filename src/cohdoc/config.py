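"""Analysis configuration: cutoffs and tables shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .calcium import CA_LIGAND_CUTOFF
from .interface import (
    HBOND_DISTANCE_CUTOFF,
    HYDROPHOBIC_CUTOFF,
    SALT_BRIDGE_CUTOFF,
)
from .itc import DEFAULT_TEMPERATURE
from .symmetry import RESIDUE_CLASSES


@dataclass
class AnalysisConfig:
    hbond_cutoff: float = HBOND_DISTANCE_CUTOFF        # Å
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF     # Å
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF     # Å
    ca_ligand_cutoff: float = CA_LIGAND_CUTOFF         # Å
    rmsd_atom_set: str = "ca"                          # "ca" | "main"
    temperature: float = DEFAULT_TEMPERATURE           # K
    seed: int | None = None
    compatibility_classes: dict[str, str] = field(
        default_factory=lambda: dict(RESIDUE_CLASSES)
    )

    def __post_init__(self) -> None:
        for name in ("hbond_cutoff", "salt_bridge_cutoff", "hydrophobic_cutoff",
                     "ca_ligand_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        missing = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"
                   if aa not in self.compatibility_classes]
        if missing:
            raise ValueError(f"compatibility classes missing residues: {missing}")

    def snapshot(self) -> dict:
        """JSON-serializable copy, embedded in reports for reproducibility."""
        return asdict(self)

    def with_overrides(self, overrides: dict[str, str]) -> "AnalysisConfig":
        """Apply key=value overrides (numbers parsed; used by the CLI)."""
        data = asdict(self)
        for key, value in overrides.items():
            if key not in data:
                raise KeyError(f"unknown config key {key!r}")
            current = data[key]
            if isinstance(current, float):
                data[key] = float(value)
            elif isinstance(current, int) and not isinstance(current, bool):
                data[key] = int(value)
            else:
                data[key] = value
        return AnalysisConfig(**data)
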