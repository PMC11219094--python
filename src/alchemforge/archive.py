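"""On-disk simulation archives.

A replica-exchange run records, on a common iteration grid: the reduced
potential of every replica at every alchemical state (``u_kln``), the
replica -> state permutation trace, the dU/dlambda trace per replica, any
registered degree-of-freedom observables, and swap acceptance counts.
Archives round-trip through HDF5 (groups /u_kln, /state_trace, /du_dl,
/dof/<name>, /meta) and can be exported to CSV per trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SCHEMA_VERSION = "alchemforge-archive-1"


@dataclass
class SimulationArchive:
    """Recorded output of one AREX/AREST run.

    Shapes: ``u_kln`` (n_iterations, K, K) with ``u_kln[n, k, l]`` the
    reduced potential of replica k's configuration at state l in iteration
    n; ``state_trace`` (n_iterations, K) the state index of replica k;
    ``du_dl`` (n_iterations, K); each DOF trace (n_iterations, K).
    """

    u_kln: np.ndarray
    state_trace: np.ndarray
    du_dl: np.ndarray
    dof_traces: dict[str, np.ndarray] = field(default_factory=dict)
    dof_categories: dict[str, str] = field(default_factory=dict)
    acceptance_counts: np.ndarray | None = None  # (K, K) accepted swaps
    attempt_counts: np.ndarray | None = None  # (K, K) attempted swaps
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u_kln = np.asarray(self.u_kln, dtype=float)
        self.state_trace = np.asarray(self.state_trace, dtype=int)
        self.du_dl = np.asarray(self.du_dl, dtype=float)

    @property
    def n_iterations(self) -> int:
        return self.u_kln.shape[0]

    @property
    def n_states(self) -> int:
        return self.u_kln.shape[1]

    def validate(self) -> None:
        n, K, K2 = self.u_kln.shape
        if K != K2:
            raise ValueError("u_kln must be (n, K, K)")
        if not np.all(np.isfinite(self.u_kln)):
            raise ValueError("non-finite reduced potentials")
        if self.state_trace.shape != (n, K):
            raise ValueError("state_trace shape mismatch")
        ref = np.arange(K)
        for row in self.state_trace:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("state_trace row is not a permutation")
        for name, tr in self.dof_traces.items():
            if tr.shape != (n, K):
                raise ValueError(f"dof trace {name!r} off the recording grid")

    # -- replica-indexed views ---------------------------------------------

    def replica_series(self, name: str, replica: int) -> np.ndarray:
        """Time series of one observable along one replica trajectory."""
        if name == "du_dl":
            return self.du_dl[:, replica]
        return self.dof_traces[name][:, replica]

    def self_reduced_potentials(self) -> np.ndarray:
        """(n, K): each replica's energy at its own current state."""
        n, K, _ = self.u_kln.shape
        rows = np.arange(n)[:, None]
        reps = np.arange(K)[None, :]
        return self.u_kln[rows, reps, self.state_trace]

    def truncated(self, n_iterations: int) -> "SimulationArchive":
        """Prefix of the archive (first ``n_iterations`` records)."""
        return SimulationArchive(
            u_kln=self.u_kln[:n_iterations],
            state_trace=self.state_trace[:n_iterations],
            du_dl=self.du_dl[:n_iterations],
            dof_traces={k: v[:n_iterations] for k, v in self.dof_traces.items()},
            dof_categories=dict(self.dof_categories),
            acceptance_counts=self.acceptance_counts,
            attempt_counts=self.attempt_counts,
            metadata=dict(self.metadata),
        )

    # -- IO -----------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema"] = SCHEMA_VERSION
            f.create_dataset("u_kln", data=self.u_kln)
            f.create_dataset("state_trace", data=self.state_trace)
            f.create_dataset("du_dl", data=self.du_dl)
            g = f.create_group("dof")
            for name, tr in self.dof_traces.items():
                d = g.create_dataset(name, data=tr)
                d.attrs["category"] = self.dof_categories.get(name, "custom")
            if self.acceptance_counts is not None:
                f.create_dataset("acceptance_counts", data=self.acceptance_counts)
            if self.attempt_counts is not None:
                f.create_dataset("attempt_counts", data=self.attempt_counts)
            f.create_group("meta").attrs["json"] = json.dumps(self.metadata)

    @classmethod
    def from_hdf5(cls, path) -> "SimulationArchive":
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != SCHEMA_VERSION:
                raise ValueError(f"unsupported archive schema {f.attrs.get('schema')!r}")
            dof_traces, dof_cat = {}, {}
            for name, d in f["dof"].items():
                dof_traces[name] = d[...]
                dof_cat[name] = d.attrs.get("category", "custom")
            return cls(
                u_kln=f["u_kln"][...],
                state_trace=f["state_trace"][...],
                du_dl=f["du_dl"][...],
                dof_traces=dof_traces,
                dof_categories=dof_cat,
                acceptance_counts=f["acceptance_counts"][...]
                if "acceptance_counts" in f
                else None,
                attempt_counts=f["attempt_counts"][...]
                if "attempt_counts" in f
                else None,
                metadata=json.loads(f["meta"].attrs["json"]),
            )

    def export_csv(self, directory) -> list[Path]:
        """Write one CSV per trace (state trace, du/dl, each DOF)."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        K = self.n_states
        cols = [f"replica_{k}" for k in range(K)]
        for name, data in [
            ("state_trace", self.state_trace),
            ("du_dl", self.du_dl),
            *self.dof_traces.items(),
        ]:
            p = directory / f"{name}.csv"
            pd.DataFrame(data, columns=cols).to_csv(p, index_label="iteration")
            written.append(p)
        return written
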