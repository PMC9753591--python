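"""Electronic-structure backend: method, basis and field for subsystem jobs.

A :class:`Backend` bundles everything needed to solve one monomer or dimer
subsystem — basis library, SCF settings, field vector/treatment and the
correlation level — so that the embedding loop, the many-body assembly and
the worker pool all dispatch through the same picklable object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import load_basis_library
from .cluster import Cluster
from .integrals import PointCharge
from .scf import (
    SCFResult,
    SCFSettings,
    build_ghost_basis,
    build_subsystem_basis,
    mp2_energy,
    scf_solve,
)


@dataclass
class Backend:
    """Solver configuration for subsystem calculations.

    ``method`` is ``"hf"`` or ``"hf+mp2"``; the field treatment lives in
    ``scf.field_treatment`` (``none`` at B = 0, else ``cgo`` or ``lao``).
    """

    basis: str | dict = "sto-3g"
    method: str = "hf"
    scf: SCFSettings = field(default_factory=SCFSettings)
    B: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gauge_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.gauge_origin = np.asarray(self.gauge_origin, dtype=float)
        if self.method not in ("hf", "hf+mp2"):
            raise ValueError(f"unknown method {self.method!r}")
        if isinstance(self.basis, str):
            self.basis = load_basis_library(self.basis)
        if np.any(self.B != 0.0):
            if self.scf.field_treatment == "none":
                raise ValueError(
                    "a finite field requires field_treatment 'cgo' or 'lao'")
            if self.scf.spin_model != "ghf":
                self.scf = replace(self.scf, spin_model="ghf")

    @classmethod
    def for_cluster(cls, cluster: Cluster, basis="sto-3g", method="hf",
                    field_treatment: str | None = None,
                    scf: SCFSettings | None = None) -> "Backend":
        """Backend matching a cluster's field: RHF at zero field, LAO-GHF
        (default) otherwise, with the cluster's gauge origin."""
        has_field = bool(np.any(cluster.B != 0.0))
        if field_treatment is None:
            field_treatment = "lao" if has_field else "none"
        base = scf or SCFSettings()
        base = replace(base, field_treatment=field_treatment,
                       spin_model="ghf" if (has_field or field_treatment
                                            != "none") else base.spin_model)
        return cls(basis=basis, method=method, scf=base, B=cluster.B.copy(),
                   gauge_origin=np.asarray(cluster.gauge_origin, dtype=float))

    def solve(self, cluster: Cluster, indices,
              charges: list[PointCharge] = (),
              ghost_active: int | None = None,
              guess_density=None) -> SCFResult:
        """SCF-solve one subsystem (``indices``); with ``ghost_active`` set,
        all other monomers of the subsystem become ghost (basis-only) atoms
        and the electron count is that of the active monomer."""
        indices = tuple(sorted(indices))
        if ghost_active is None:
            basis = build_subsystem_basis(cluster, indices, self.basis)
            nelec = sum(cluster.monomers[i].n_electrons for i in indices)
        else:
            basis = build_ghost_basis(cluster, indices, ghost_active,
                                      self.basis)
            nelec = cluster.monomers[ghost_active].n_electrons
        return scf_solve(
            basis, nelec, charges=list(charges), B=self.B,
            gauge_origin=self.gauge_origin, settings=self.scf,
            guess_density=guess_density)

    def total_energy(self, result: SCFResult) -> float:
        """SCF energy plus MP2 correlation when the method requests it."""
        result.require_converged()
        if self.method == "hf+mp2":
            return result.energy + mp2_energy(result)
        return result.energy
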