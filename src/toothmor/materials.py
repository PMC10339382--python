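"""Constitutive parameter sets for the tissue regions.

Dentin and alveolar bone are modelled as homogeneous linear-elastic solids
(Saint Venant–Kirchhoff in the finite-strain solver, which coincides with
linear elasticity at small strain). The periodontal ligament uses the
first-order compressible Ogden law (see :mod:`toothmor.ogden`).

Default moduli for the hard tissues are literature-typical values for human
dentin and mandibular cortical bone. The ligament defaults (μ = 0.5 MPa,
α = 10, D set for an effective ground-state Poisson ratio of 0.45) describe
a compliant, strongly strain-stiffening, nearly incompressible soft tissue;
experimental fits for the ligament span orders of magnitude, and these
values are configurable placeholders chosen so the tissue carries occlusal
loads at moderate (tens of percent) strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

from .exceptions import MaterialError
from .geometry import Region

__all__ = ["Material", "MaterialSet", "default_materials"]


@dataclass(frozen=True)
class Material:
    """One region's constitutive model.

    ``kind`` selects the law: ``"linear_elastic"`` (parameters ``E`` MPa,
    ``nu``) or ``"ogden1"`` (parameters ``mu`` MPa, ``alpha``, ``D`` MPa⁻¹).
    """

    kind: str
    E: float = 0.0
    nu: float = 0.0
    mu: float = 0.0
    alpha: float = 0.0
    D: float = 0.0

    def validate(self) -> None:
        if self.kind == "linear_elastic":
            if not self.E > 0:
                raise MaterialError("linear_elastic requires E > 0")
            if not (-1.0 < self.nu < 0.5):
                raise MaterialError("linear_elastic requires -1 < nu < 0.5")
        elif self.kind == "ogden1":
            if not self.mu > 0:
                raise MaterialError("ogden1 requires mu > 0")
            if self.alpha == 0:
                raise MaterialError("ogden1 requires alpha != 0")
            if not self.D > 0:
                raise MaterialError("ogden1 requires D > 0")
        else:
            raise MaterialError(f"unknown material kind {self.kind!r}")

    @property
    def lame(self):
        """Lamé constants (λ, μ) for a linear-elastic material."""
        if self.kind != "linear_elastic":
            raise MaterialError("Lamé constants only defined for linear_elastic")
        lam = self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = self.E / (2.0 * (1.0 + self.nu))
        return lam, mu


class MaterialSet:
    """Mapping of :class:`~toothmor.geometry.Region` to :class:`Material`."""

    def __init__(self, per_region: Dict[Region, Material]):
        self.per_region = {Region(k): v for k, v in per_region.items()}
        for mat in self.per_region.values():
            mat.validate()

    def __getitem__(self, region: Region) -> Material:
        return self.per_region[Region(region)]

    def validate_covers(self, regions: Iterable[int]) -> None:
        missing = {Region(r).name for r in set(regions)} - {
            r.name for r in self.per_region
        }
        if missing:
            raise MaterialError(f"materials missing for regions: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            Region(r).name: {
                "kind": m.kind,
                "E": m.E,
                "nu": m.nu,
                "mu": m.mu,
                "alpha": m.alpha,
                "D": m.D,
            }
            for r, m in self.per_region.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSet":
        return cls({Region[name]: Material(**params) for name, params in d.items()})


def ogden_D_for_poisson(mu: float, nu_eff: float) -> float:
    """Compressibility D giving a ground-state Poisson ratio ``nu_eff``.

    Ground-state bulk modulus of the Ogden law is K = 2/D; imposing the
    isotropic relation K/μ = 2(1+ν)/(3(1−2ν)) fixes D.
    """
    K = 2.0 * mu * (1.0 + nu_eff) / (3.0 * (1.0 - 2.0 * nu_eff))
    return 2.0 / K


def default_materials() -> MaterialSet:
    """Package defaults: stiff dentin and bone, soft stiffening ligament."""
    return MaterialSet(
        {
            Region.DENTIN: Material(kind="linear_elastic", E=18600.0, nu=0.31),
            Region.BONE: Material(kind="linear_elastic", E=13700.0, nu=0.30),
            Region.PDL: Material(
                kind="ogden1", mu=0.5, alpha=10.0, D=ogden_D_for_poisson(0.5, 0.45)
            ),
        }
    )
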