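"""Tissue property tables.

Electrical and thermal properties for the tissues of the synthetic torso
phantom.  Conductivities anchor to the values quoted for the low-frequency
(kHz) regime — close to 0 S/m for internal air, 0.36 S/m for muscle and
3 S/m for urine — with high-frequency (MHz) values scaled up per tissue.
The temperature coefficient of conductivity is taken as 2 %/degC for all
tissues and the effective plasma fractions as 24 % (LF) and 8 % (HF).

The numbers are a compact approximation in the spirit of the IT'IS tissue
database; every value can be overridden through :class:`TissueTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping

__all__ = [
    "TissueProperties",
    "TissueTable",
    "default_tissue_table",
    "BLOOD_DENSITY",
    "BLOOD_SPECIFIC_HEAT",
    "BODY_TEMPERATURE",
]

#: Density of blood (kg/m^3) and its specific heat (J/(kg degC)); the
#: arterial blood temperature used as the body-core reference (degC).
BLOOD_DENSITY = 1050.0
BLOOD_SPECIFIC_HEAT = 3617.0
BODY_TEMPERATURE = 37.0


@dataclass(frozen=True)
class TissueProperties:
    """Electrical and thermal properties of one tissue.

    Parameters
    ----------
    name:
        Text label, used as the mesh/tissue-table key.
    sigma_lf, sigma_hf:
        Electrical conductivity (S/m) at the low- and high-frequency
        operating points.
    tc:
        Temperature coefficient of conductivity (fraction per degC).
    alpha_lf, alpha_hf:
        Effective plasma/extracellular volume fraction at each frequency
        (dimensionless, in [0, 1)).
    rho:
        Density (kg/m^3).
    c:
        Specific heat capacity (J/(kg degC)).
    k:
        Thermal conductivity (W/(m degC)).
    wb0:
        Baseline perfusion rate (kg/(s m^3)).
    qm:
        Metabolic heat generation (W/m^3).  Defaults to zero: the uniform
        37 degC baseline is interpreted as the equilibrium in which
        metabolic heat is already balanced.
    perfusion_responsive:
        Whether heating-induced perfusion changes contribute to the
        conductivity of this tissue (muscle, fat and tumor by default).
    """

    name: str
    sigma_lf: float
    sigma_hf: float
    tc: float = 0.02
    alpha_lf: float = 0.24
    alpha_hf: float = 0.08
    rho: float = 1050.0
    c: float = 3600.0
    k: float = 0.5
    wb0: float = 0.0
    qm: float = 0.0
    perfusion_responsive: bool = False

    def __post_init__(self) -> None:
        if self.sigma_lf < 0 or self.sigma_hf < 0:
            raise ValueError(f"{self.name}: conductivities must be >= 0")
        if not (0.0 <= self.alpha_lf < 1.0 and 0.0 <= self.alpha_hf < 1.0):
            raise ValueError(f"{self.name}: alpha must lie in [0, 1)")
        if self.tc < 0:
            raise ValueError(f"{self.name}: temperature coefficient must be >= 0")

    def sigma(self, frequency_tag: str) -> float:
        """Conductivity (S/m) for a frequency tag ``'lf'`` or ``'hf'``."""
        if frequency_tag == "lf":
            return self.sigma_lf
        if frequency_tag == "hf":
            return self.sigma_hf
        raise ValueError(f"unknown frequency tag {frequency_tag!r}")

    def alpha(self, frequency_tag: str) -> float:
        """Plasma fraction for a frequency tag ``'lf'`` or ``'hf'``."""
        if frequency_tag == "lf":
            return self.alpha_lf
        if frequency_tag == "hf":
            return self.alpha_hf
        raise ValueError(f"unknown frequency tag {frequency_tag!r}")


class TissueTable:
    """Ordered mapping of tissue name -> :class:`TissueProperties`.

    Tissue ids (integers used as mesh element labels) are assigned by
    insertion order.
    """

    def __init__(self, tissues: Iterable[TissueProperties]):
        self._by_name: Dict[str, TissueProperties] = {}
        for t in tissues:
            if t.name in self._by_name:
                raise ValueError(f"duplicate tissue {t.name!r}")
            self._by_name[t.name] = t
        self._names = list(self._by_name)

    # -- mapping-like access -------------------------------------------------
    def __getitem__(self, name: str) -> TissueProperties:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def id_of(self, name: str) -> int:
        return self._names.index(name)

    def name_of(self, tissue_id: int) -> str:
        return self._names[tissue_id]

    def by_id(self, tissue_id: int) -> TissueProperties:
        return self._by_name[self._names[tissue_id]]

    # -- vectorized property lookup ------------------------------------------
    def property_array(self, labels, attr: str):
        """Per-element array of ``attr`` for integer tissue labels."""
        import numpy as np

        labels = np.asarray(labels)
        values = np.array([getattr(self.by_id(i), attr) for i in range(len(self))], dtype=float)
        return values[labels]

    def sigma_array(self, labels, frequency_tag: str):
        attr = "sigma_lf" if frequency_tag == "lf" else "sigma_hf"
        if frequency_tag not in ("lf", "hf"):
            raise ValueError(f"unknown frequency tag {frequency_tag!r}")
        return self.property_array(labels, attr)

    def updated(self, name: str, **changes) -> "TissueTable":
        """Return a copy of the table with one tissue's fields replaced."""
        tissues = [replace(t, **changes) if t.name == name else t for t in self]
        return TissueTable(tissues)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, float]]) -> "TissueTable":
        """Build a table from a nested ``{name: {field: value}}`` mapping."""
        return cls(TissueProperties(name=name, **dict(fields)) for name, fields in mapping.items())


def default_tissue_table() -> TissueTable:
    """The packaged default tissue table for the synthetic torso phantom.

    Muscle (0.36 S/m) and urine (3.0 S/m) anchor the low-frequency spread of
    the phantom; internal air sits at 0 S/m.  Thermal values are rounded
    literature magnitudes.
    """
    return TissueTable(
        [
            TissueProperties("muscle", 0.36, 0.50, rho=1090.0, c=3421.0, k=0.49,
                             wb0=0.67, perfusion_responsive=True),
            TissueProperties("fat", 0.04, 0.06, rho=911.0, c=2348.0, k=0.21,
                             wb0=0.50, perfusion_responsive=True),
            TissueProperties("skin", 0.10, 0.25, rho=1109.0, c=3391.0, k=0.37,
                             wb0=1.80),
            TissueProperties("bone", 0.02, 0.04, rho=1908.0, c=1313.0, k=0.32,
                             wb0=0.18),
            TissueProperties("organ", 0.08, 0.15, rho=1079.0, c=3540.0, k=0.52,
                             wb0=8.0),
            TissueProperties("urine", 3.00, 3.00, rho=1000.0, c=4180.0, k=0.60,
                             wb0=0.0),
            TissueProperties("tumor", 0.30, 0.45, rho=1050.0, c=3800.0, k=0.55,
                             wb0=0.80, perfusion_responsive=True),
            TissueProperties("air_internal", 0.0, 0.0, rho=1.2, c=1005.0, k=0.026,
                             wb0=0.0),
        ]
    )
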