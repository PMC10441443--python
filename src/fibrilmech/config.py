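"""Validated run configuration (YAML-backed) and its mapping onto the model.

The schema mirrors the model structure: a geometry block (molecule + fibril),
a force-field block (three trilinear bond families, pair, angle), a cross-link
block (density, mandatory seed, insertion cutoff), a protocol block and an
output block.  Unknown keys are rejected; every run can archive its resolved
configuration together with a content hash for exact re-derivation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from fibrilmech.forcefield import (
    AngleSpec,
    ForceField,
    PairSpec,
    TrilinearBondSpec,
    COLLAGEN_BOND,
    GLUCOSEPANE,
    STRENGTHENED_BOND,
)
from fibrilmech.geometry import (
    CrossLinkSet,
    FibrilSpec,
    FibrilTopology,
    TCMoleculeSpec,
    build_fibril,
    insert_crosslinks,
)
from fibrilmech.tensile import PullProtocol


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MoleculeConfig(_Block):
    n_particles: int = 218
    spacing: float = 14.0
    diameter_sigma: float = 14.72
    crimp_ratio: float = 1.0

    def to_spec(self) -> TCMoleculeSpec:
        return TCMoleculeSpec(**self.model_dump())


class FibrilConfig(_Block):
    d_period: float = 670.0
    gap_fraction: float = 0.6
    n_periods: int = 5
    fibril_diameter: float = 202.0
    end_extension_particles: int = 40
    lattice_spacing: float | None = None

    def to_spec(self) -> FibrilSpec:
        return FibrilSpec(**self.model_dump())


class GeometryConfig(_Block):
    molecule: MoleculeConfig = Field(default_factory=MoleculeConfig)
    fibril: FibrilConfig = Field(default_factory=FibrilConfig)


class BondConfig(_Block):
    r0: float
    r1: float
    rbreak: float
    k0: float
    k1: float
    z: float = 0.1

    def to_spec(self) -> TrilinearBondSpec:
        return TrilinearBondSpec(**self.model_dump())

    @classmethod
    def from_spec(cls, spec: TrilinearBondSpec) -> "BondConfig":
        return cls(r0=spec.r0, r1=spec.r1, rbreak=spec.rbreak,
                   k0=spec.k0, k1=spec.k1, z=spec.z)


class PairConfig(_Block):
    sigma: float = 14.72
    epsilon: float = 6.87
    cutoff: float = 36.8
    switch_on: float = 0.9
    max_force: float = 1.0e4

    def to_spec(self) -> PairSpec:
        return PairSpec(**self.model_dump())


class AngleConfig(_Block):
    k_bend: float = 14.98
    theta0: float | None = None  # None: native (as-built) angles

    def to_spec(self) -> AngleSpec:
        return AngleSpec(**self.model_dump())


class ForceFieldConfig(_Block):
    collagen: BondConfig = Field(default_factory=lambda: BondConfig.from_spec(COLLAGEN_BOND))
    age: BondConfig = Field(default_factory=lambda: BondConfig.from_spec(GLUCOSEPANE))
    strengthened: BondConfig = Field(
        default_factory=lambda: BondConfig.from_spec(STRENGTHENED_BOND)
    )
    pair: PairConfig | None = Field(default_factory=PairConfig)
    angle: AngleConfig | None = Field(default_factory=AngleConfig)

    def to_forcefield(self) -> ForceField:
        return ForceField(
            collagen=self.collagen.to_spec(),
            age=self.age.to_spec(),
            strengthened=self.strengthened.to_spec(),
            pair=self.pair.to_spec() if self.pair else None,
            angle=self.angle.to_spec() if self.angle else None,
        )


class CrosslinkConfig(_Block):
    n_age: float = 0.0
    seed: int  # mandatory
    insertion_cutoff: float = 20.62

    def to_spec(self) -> CrossLinkSet:
        return CrossLinkSet(n_age=self.n_age, rng_seed=self.seed,
                            insertion_cutoff=self.insertion_cutoff)


class ProtocolConfig(_Block):
    mode: Literal["quasistatic", "dynamic"] = "quasistatic"
    velocity: float = 1.0e-4
    timestep: float = 1.0
    strain_target: float = 0.6
    sample_interval: int = 1
    displacement_increment: float | None = None
    minimizer_gtol: float = 1.0e-3
    minimizer_maxiter: int = 2000
    stop_fraction: float = 0.05
    temperature: float = 300.0
    damping: float = 1000.0
    mass: float = 1360.0

    def to_protocol(self) -> PullProtocol:
        return PullProtocol(**self.model_dump())


class OutputConfig(_Block):
    directory: str = "results"
    curve_csv: bool = True
    xyz: bool = False
    lammps_dump: bool = False
    write_positions: bool = False


class RunConfig(_Block):
    """Complete, schema-validated description of one tensile-test run."""

    preset: str | None = None
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    forcefield: ForceFieldConfig = Field(default_factory=ForceFieldConfig)
    crosslinks: CrosslinkConfig
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Deterministic sha256 of the resolved configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- model construction -------------------------------------------------
    def build_topology(self) -> FibrilTopology:
        if self.preset in ("single-bond", "two-chain"):
            from fibrilmech.fixtures import make_fixture

            return make_fixture(self.preset, seed=self.crosslinks.seed)[1]
        topo = build_fibril(self.geometry.fibril.to_spec(), self.geometry.molecule.to_spec())
        return insert_crosslinks(topo, self.crosslinks.to_spec())

    def build_forcefield(self) -> ForceField:
        return self.forcefield.to_forcefield()

    def build_protocol(self) -> PullProtocol:
        return self.protocol.to_protocol()
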