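"""Per-step simulation trace with repr-exact CSV serialization.

Each row records one equilibrium (row 0 is the initial state): the signed
input, node count, convergence diagnostics, the energy breakdown, and the
stacked node positions x, y, z per node.  Rows are ragged (the node count
changes as the catheter is pushed and pulled), so the trace uses its own
CSV reader/writer; floats are written with ``repr`` so a parsed trace is
numerically identical to the one in memory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

_FIXED_COLUMNS = [
    "step", "input_mm", "n_nodes", "converged", "outer_iterations",
    "potential", "elastic_energy", "contact_energy", "external_work",
    "gradient_residual", "max_penetration_mm", "tangent_norm_drift",
    "inserted_length_mm",
]


@dataclass
class StepRecord:
    step: int
    input_mm: float
    n_nodes: int
    converged: bool
    outer_iterations: int
    potential: float
    elastic_energy: float
    contact_energy: float
    external_work: float
    gradient_residual: float
    max_penetration_mm: float
    tangent_norm_drift: float
    inserted_length_mm: float
    positions: np.ndarray  # (n_nodes, 3)

    @classmethod
    def from_result(cls, step: int, input_mm: float, result, inserted_length: float) -> "StepRecord":
        return cls(
            step=step,
            input_mm=input_mm,
            n_nodes=result.state.n_nodes,
            converged=result.converged,
            outer_iterations=result.outer_iterations,
            potential=result.potential,
            elastic_energy=result.elastic_energy,
            contact_energy=result.contact_energy,
            external_work=result.external_work,
            gradient_residual=result.gradient_residual,
            max_penetration_mm=result.contacts.max_penetration(),
            tangent_norm_drift=result.tangent_norm_drift,
            inserted_length_mm=inserted_length,
            positions=np.asarray(result.positions, float),
        )

    def to_row(self) -> list:
        r = lambda v: repr(float(v))  # shortest round-trip decimal form
        row = [
            self.step, r(self.input_mm), self.n_nodes, int(self.converged),
            self.outer_iterations, r(self.potential), r(self.elastic_energy),
            r(self.contact_energy), r(self.external_work),
            r(self.gradient_residual), r(self.max_penetration_mm),
            r(self.tangent_norm_drift), r(self.inserted_length_mm),
        ]
        for p in self.positions:
            row.extend([r(p[0]), r(p[1]), r(p[2])])
        return row

    @classmethod
    def from_row(cls, row: list) -> "StepRecord":
        n_nodes = int(row[2])
        coords = [float(v) for v in row[len(_FIXED_COLUMNS):]]
        if len(coords) != 3 * n_nodes:
            raise ValidationError("trace row coordinate count does not match n_nodes")
        return cls(
            step=int(row[0]),
            input_mm=float(row[1]),
            n_nodes=n_nodes,
            converged=bool(int(row[3])),
            outer_iterations=int(row[4]),
            potential=float(row[5]),
            elastic_energy=float(row[6]),
            contact_energy=float(row[7]),
            external_work=float(row[8]),
            gradient_residual=float(row[9]),
            max_penetration_mm=float(row[10]),
            tangent_norm_drift=float(row[11]),
            inserted_length_mm=float(row[12]),
            positions=np.array(coords, float).reshape(n_nodes, 3),
        )


@dataclass
class SimulationTrace:
    """Ordered equilibrium records; row count = number of inputs + 1."""

    records: list = field(default_factory=list)

    def append(self, record: StepRecord) -> None:
        self.records.append(record)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i) -> StepRecord:
        return self.records[i]

    @property
    def final_positions(self) -> np.ndarray:
        return self.records[-1].positions

    def all_converged(self) -> bool:
        return all(r.converged for r in self.records)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_FIXED_COLUMNS + ["x0", "y0", "z0", "..."])
            for rec in self.records:
                writer.writerow(rec.to_row())

    @classmethod
    def read_csv(cls, path) -> "SimulationTrace":
        path = Path(path)
        trace = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
                raise ValidationError(f"{path}: not a cathsim trace file")
            for row in reader:
                if row:
                    trace.append(StepRecord.from_row(row))
        return trace

    def summary(self) -> dict:
        last = self.records[-1]
        return {
            "n_steps": len(self.records) - 1,
            "all_converged": self.all_converged(),
            "final_n_nodes": last.n_nodes,
            "final_potential": last.potential,
            "final_elastic_energy": last.elastic_energy,
            "final_contact_energy": last.contact_energy,
            "final_max_penetration_mm": last.max_penetration_mm,
            "final_gradient_residual": last.gradient_residual,
            "max_tangent_norm_drift": max(r.tangent_norm_drift for r in self.records),
            "final_inserted_length_mm": last.inserted_length_mm,
        }
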