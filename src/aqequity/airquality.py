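"""Source-receptor PM2.5 modeling.

The source-receptor matrix (SRM) is a linear operator: for each pollutant
and release layer, a source-cell × receptor-cell matrix of annual-average
concentration response (µg/m³ per metric ton/yr).  Each emitted pollutant
maps one-to-one to a PM2.5 species (primary PM2.5, particulate sulfate /
nitrate / ammonium, SOA); total PM2.5 is the species sum plus any constant
background.  Everything here is linear, so fields superpose and sector
contributions add exactly to the total scenario delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, LabelError, ShapeError
from .inventory import ESHLayer, POLLUTANTS, EmissionSource

#: One-to-one mapping from emitted pollutant to the PM2.5 species it forms.
SPECIES_MAP = {
    "pm25": "primary_pm25",
    "so2": "pSO4",
    "nox": "pNO3",
    "nh3": "pNH4",
    "voc": "SOA",
}
SPECIES = tuple(SPECIES_MAP[p] for p in POLLUTANTS)


@dataclass
class SourceReceptorMatrix:
    """Per-(pollutant, layer) source → receptor concentration response.

    ``matrices[(pollutant, layer)]`` is an (n_cells, n_cells) array, entry
    [s, r] = µg/m³ at receptor cell r per metric ton/yr emitted in source
    cell s. Entries are non-negative; all matrices share one grid.
    """

    matrices: dict[tuple[str, ESHLayer], np.ndarray]
    n_cells: int

    def __post_init__(self) -> None:
        for key, m in self.matrices.items():
            if m.shape != (self.n_cells, self.n_cells):
                raise ShapeError(f"SRM block {key} has shape {m.shape}, expected "
                                 f"({self.n_cells}, {self.n_cells})")
            if (m < 0).any():
                raise ShapeError(f"SRM block {key} has negative entries")

    def matrix(self, pollutant: str, layer: ESHLayer) -> np.ndarray:
        try:
            return self.matrices[(pollutant, layer)]
        except KeyError:
            raise CoverageError(f"SRM has no block for (pollutant={pollutant!r}, "
                                f"layer={layer.value})") from None

    def save(self, path) -> None:
        """Write to an .npz container; round-trips bit-exactly."""
        arrays = {f"{p}__{layer.value}": m for (p, layer), m in self.matrices.items()}
        np.savez(path, n_cells=np.array(self.n_cells), **arrays)

    @classmethod
    def load(cls, path) -> "SourceReceptorMatrix":
        with np.load(path) as data:
            n_cells = int(data["n_cells"])
            matrices = {}
            for key in data.files:
                if key == "n_cells":
                    continue
                p, layer = key.split("__")
                matrices[(p, ESHLayer(layer))] = data[key]
        return cls(matrices=matrices, n_cells=n_cells)


@dataclass
class ConcentrationField:
    """Species-resolved PM2.5 concentrations (µg/m³) per receptor cell."""

    species: dict[str, np.ndarray]
    background: float | np.ndarray = 0.0

    @property
    def n_cells(self) -> int:
        return len(next(iter(self.species.values())))

    @property
    def total(self) -> np.ndarray:
        """Total PM2.5 = species sum + background, cell-wise."""
        out = np.zeros(self.n_cells)
        for arr in self.species.values():
            out = out + arr
        return out + self.background


def apply_srm(inventory: list[EmissionSource], srm: SourceReceptorMatrix,
              background: float | np.ndarray = 0.0) -> ConcentrationField:
    """Concentration field from an inventory: species = Σ emission × SRM row.

    Every source must carry a resolved ESH layer. Linear in emissions.
    """
    # Accumulate emissions into per-(pollutant, layer) source-cell vectors
    # so each SRM block is applied once.
    emis: dict[tuple[str, ESHLayer], np.ndarray] = {}
    for s in inventory:
        if s.esh_layer is None:
            raise CoverageError(f"source {s.id} has no resolved ESH layer")
        for p in POLLUTANTS:
            m = s.mass(p)
            if m == 0.0:
                continue
            key = (p, s.esh_layer)
            if key not in srm.matrices:
                raise CoverageError(f"SRM has no block for (pollutant={p!r}, "
                                    f"layer={s.esh_layer.value})")
            vec = emis.setdefault(key, np.zeros(srm.n_cells))
            vec[s.cell] += m

    species = {name: np.zeros(srm.n_cells) for name in SPECIES}
    for (p, layer), vec in emis.items():
        species[SPECIES_MAP[p]] += vec @ srm.matrices[(p, layer)]
    return ConcentrationField(species=species, background=background)


def concentration_delta(a: ConcentrationField, b: ConcentrationField) -> ConcentrationField:
    """Cell-wise a − b per species; constant backgrounds cancel."""
    if a.n_cells != b.n_cells or set(a.species) != set(b.species):
        raise ShapeError("concentration fields are on different grids or species sets")
    bg = np.asarray(a.background) - np.asarray(b.background)
    return ConcentrationField(
        species={k: a.species[k] - b.species[k] for k in a.species},
        background=float(bg) if bg.ndim == 0 else bg,
    )


def sector_contribution(inv_base: list[EmissionSource], inv_policy: list[EmissionSource],
                        srm: SourceReceptorMatrix, sector: str) -> ConcentrationField:
    """Policy − baseline concentration change attributable to one sector.

    By linearity, contributions over all sectors sum exactly to the total
    scenario delta.
    """
    sectors = {s.sector for s in inv_base} | {s.sector for s in inv_policy}
    if sector not in sectors:
        raise LabelError(f"unknown sector {sector!r}; inventory has {sorted(sectors)}")
    base = [s for s in inv_base if s.sector == sector]
    policy = [s for s in inv_policy if s.sector == sector]
    return concentration_delta(apply_srm(policy, srm), apply_srm(base, srm))
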