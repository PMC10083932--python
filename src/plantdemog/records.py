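"""Stage-structured projection-matrix records: data model, eligibility
filtering, and eigen-analysis.

A matrix population model projects a stage-abundance vector one year
forward, ``n(t+1) = A n(t)``.  The projection matrix decomposes as
``A = T + F``: ``T`` holds survival/growth transition probabilities
(column ``j`` sums to the annual survival of stage ``j``) and ``F``
holds per-capita sexual offspring.  Records carry the study metadata
needed to decide whether a published matrix is usable for comparative
analysis (natural conditions, annual time step, stage/size
classification, and so on).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ProjectionMatrixRecord",
    "EigenTriple",
    "StructuralError",
    "validate_record",
    "survival_issue",
    "is_irreducible",
    "dominant_eigen",
    "read_records",
    "write_records",
    "CONDITION_DESCRIPTIONS",
]

TREATMENTS = ("unmanipulated", "manipulated")
STAGE_CRITERIA = ("stage", "size", "age", "other")
COMPOSITIONS = ("mean", "pooled", "individual")

#: Eligibility conditions applied to database records before analysis.
CONDITION_DESCRIPTIONS = {
    1: "treatment is unmanipulated (natural conditions)",
    2: "survival (T) and reproduction (F) components present with A = T + F",
    3: "study duration of at least one year",
    4: "annual matrix periodicity",
    5: "individuals classified by developmental stage or size",
    6: "matrix composition is mean, pooled, or individual",
    7: "matrix dimension at least 2 x 2 stages",
    8: "survival issue < 1.05 (tolerable error in survival estimates)",
    9: "matrix irreducible (all stages connected)",
}

SURVIVAL_ISSUE_LIMIT = 1.05


class StructuralError(ValueError):
    """A record is malformed (non-square or mismatched matrices, missing
    blocks) as opposed to merely failing an eligibility condition."""


@dataclass
class RecordMetadata:
    treatment: str = "unmanipulated"
    periodicity_years: float = 1.0
    stage_criterion: str = "stage"
    composition: str = "mean"
    duration_years: float = 1.0

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "periodicity_years": self.periodicity_years,
            "stage_criterion": self.stage_criterion,
            "composition": self.composition,
            "duration_years": self.duration_years,
        }


@dataclass
class ProjectionMatrixRecord:
    """One species' annual projection matrix and its eligibility metadata.

    Parameters
    ----------
    species_id : str
        Species identifier (binomial or database accession).
    listed : bool
        Whether the species is listed as threatened/endangered under the
        US Endangered Species Act.
    T, F : ndarray
        Survival/transition and sexual-reproduction components.
    A : ndarray, optional
        Full projection matrix; reconstructed as ``T + F`` when omitted
        and cross-checked against ``T + F`` when supplied.
    """

    species_id: str
    listed: bool
    T: np.ndarray
    F: np.ndarray
    A: np.ndarray | None = None
    stages: list[str] | None = None
    metadata: RecordMetadata = field(default_factory=RecordMetadata)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        for name, M in (("T", self.T), ("F", self.F)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise StructuralError(f"{name} must be square, got shape {M.shape}")
        if self.T.shape != self.F.shape:
            raise StructuralError(
                f"T and F dimensions differ: {self.T.shape} vs {self.F.shape}"
            )
        if self.A is None:
            self.A = self.T + self.F
        else:
            self.A = np.asarray(self.A, dtype=float)
            if self.A.shape != self.T.shape:
                raise StructuralError(
                    f"A dimension {self.A.shape} does not match T {self.T.shape}"
                )
        if self.stages is None:
            self.stages = [f"stage{i + 1}" for i in range(self.n_stages)]

    @property
    def n_stages(self) -> int:
        return self.T.shape[0]

    def copy(self) -> "ProjectionMatrixRecord":
        return replace(
            self,
            T=self.T.copy(),
            F=self.F.copy(),
            A=self.A.copy(),
            stages=list(self.stages),
            metadata=RecordMetadata(**self.metadata.to_dict()),
        )


@dataclass
class EigenTriple:
    """Dominant eigenstructure of a projection matrix.

    ``lam`` is the asymptotic per-year population growth rate, ``w`` the
    stable stage distribution (right eigenvector, sums to one) and ``v``
    the reproductive values (left eigenvector, scaled so <v, w> = 1).
    """

    lam: float
    w: np.ndarray
    v: np.ndarray


def survival_issue(T: np.ndarray) -> float:
    """Maximum column sum of the survival matrix.

    Column sums of ``T`` estimate annual stage-specific survival; sums
    above one indicate estimation error, tolerated up to 1.05.
    """
    T = np.asarray(T, dtype=float)
    if T.size == 0:
        raise ValueError("empty survival matrix")
    return float(T.sum(axis=0).max())


def is_irreducible(A: np.ndarray) -> bool:
    """True iff the life-cycle graph of ``A`` is strongly connected.

    Entry ``A[i, j] > 0`` is the arc j -> i; irreducibility means every
    stage can eventually contribute individuals to every other stage.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise StructuralError(f"matrix must be square, got shape {A.shape}")
    n = A.shape[0]
    if n == 1:
        return bool(A[0, 0] > 0)
    n_comp, _ = connected_components(csr_matrix(A != 0), connection="strong")
    return n_comp == 1


def validate_record(
    rec: ProjectionMatrixRecord, atol: float = 1e-9
) -> list[int]:
    """Return the list of failed eligibility conditions (empty = accepted).

    Conditions follow the comparative-demography screening protocol:
    metadata conditions (1, 3-6) trust the supplied annotations; matrix
    conditions (2, 7-9) are computed from the record itself.  Structural
    problems raise :class:`StructuralError` instead of appearing in the
    list.
    """
    md = rec.metadata
    violations: list[int] = []
    if md.treatment != "unmanipulated":
        violations.append(1)
    if rec.T is None or rec.F is None or not np.allclose(
        rec.A, rec.T + rec.F, atol=atol, rtol=0.0
    ):
        violations.append(2)
    if md.duration_years < 1:
        violations.append(3)
    if md.periodicity_years != 1:
        violations.append(4)
    if md.stage_criterion not in ("stage", "size"):
        violations.append(5)
    if md.composition not in COMPOSITIONS:
        violations.append(6)
    if rec.n_stages < 2:
        violations.append(7)
    if not (survival_issue(rec.T) < SURVIVAL_ISSUE_LIMIT):
        violations.append(8)
    if not is_irreducible(rec.A):
        violations.append(9)
    return violations


def dominant_eigen(A: np.ndarray, imag_tol: float = 1e-10) -> EigenTriple:
    """Dominant eigenvalue and Perron eigenvectors of a non-negative matrix.

    For an irreducible non-negative matrix the Perron-Frobenius theorem
    guarantees a real dominant eigenvalue with non-negative left/right
    eigenvectors; signs are flipped to the non-negative orientation, ``w``
    normalized to sum one and ``v`` scaled so that <v, w> = 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise StructuralError(f"matrix must be square, got shape {A.shape}")
    vals, vl, vr = scipy.linalg.eig(A, left=True, right=True)
    # imprimitive (periodic) life cycles have several eigenvalues on the
    # spectral circle; the Perron root is the one with largest real part
    mods = np.abs(vals)
    near_max = mods >= mods.max() * (1.0 - 1e-9)
    candidates = np.nonzero(near_max)[0]
    idx = int(candidates[np.argmax(vals[candidates].real)])
    lam = vals[idx]
    if abs(lam.imag) > imag_tol * max(1.0, abs(lam.real)):
        raise ValueError(
            f"dominant eigenvalue has non-negligible imaginary part {lam.imag:g}"
        )
    lam = float(lam.real)
    w = np.real(vr[:, idx])
    v = np.real(vl[:, idx])
    # orient to the non-negative Perron direction
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    w = np.where(np.abs(w) < 1e-14, 0.0, w)
    v = np.where(np.abs(v) < 1e-14, 0.0, v)
    w = w / w.sum()
    v = v / float(v @ w)
    return EigenTriple(lam=lam, w=w, v=v)


# ---------------------------------------------------------------------------
# Exchange I/O
#
# JSON schema: a list of objects with keys species_id, listed, stages,
# matT, matF, matA (row-major lists of lists) and metadata{...}.
# CSV schema: long format with columns species_id, matrix (T|F|A), row, col,
# value, plus a sidecar "<stem>_metadata.csv".
# ---------------------------------------------------------------------------


def _record_to_obj(rec: ProjectionMatrixRecord) -> dict:
    return {
        "species_id": rec.species_id,
        "listed": bool(rec.listed),
        "stages": list(rec.stages),
        "matT": rec.T.tolist(),
        "matF": rec.F.tolist(),
        "matA": rec.A.tolist(),
        "metadata": rec.metadata.to_dict(),
    }


def _obj_to_record(obj: dict, index: int) -> ProjectionMatrixRecord:
    for key in ("species_id", "listed", "matT", "matF"):
        if key not in obj:
            raise StructuralError(f"record {index}: missing field '{key}'")
    md = obj.get("metadata", {})
    unknown = set(md) - set(RecordMetadata().to_dict())
    if unknown:
        raise StructuralError(
            f"record {index}: unknown metadata keys {sorted(unknown)}"
        )
    return ProjectionMatrixRecord(
        species_id=str(obj["species_id"]),
        listed=bool(obj["listed"]),
        T=np.asarray(obj["matT"], dtype=float),
        F=np.asarray(obj["matF"], dtype=float),
        A=np.asarray(obj["matA"], dtype=float) if "matA" in obj else None,
        stages=list(obj["stages"]) if "stages" in obj else None,
        metadata=RecordMetadata(**md),
    )


def write_records(
    records: Sequence[ProjectionMatrixRecord], path: str | Path, format: str = "json"
) -> None:
    """Serialize records to the JSON or CSV exchange schema."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps([_record_to_obj(r) for r in records], indent=1)
        )
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["species_id", "matrix", "row", "col", "value"])
            for rec in records:
                for name, M in (("T", rec.T), ("F", rec.F), ("A", rec.A)):
                    for i in range(rec.n_stages):
                        for j in range(rec.n_stages):
                            wr.writerow([rec.species_id, name, i, j, repr(float(M[i, j]))])
        meta_path = path.with_name(path.stem + "_metadata.csv")
        with open(meta_path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(
                [
                    "species_id",
                    "listed",
                    "stages",
                    "treatment",
                    "periodicity_years",
                    "stage_criterion",
                    "composition",
                    "duration_years",
                ]
            )
            for rec in records:
                md = rec.metadata
                wr.writerow(
                    [
                        rec.species_id,
                        int(rec.listed),
                        ";".join(rec.stages),
                        md.treatment,
                        repr(md.periodicity_years),
                        md.stage_criterion,
                        md.composition,
                        repr(md.duration_years),
                    ]
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_records(path: str | Path, format: str = "json") -> list[ProjectionMatrixRecord]:
    """Read records from the JSON or CSV exchange schema (inverse of
    :func:`write_records`)."""
    path = Path(path)
    if format == "json":
        objs = json.loads(path.read_text())
        return [_obj_to_record(obj, i) for i, obj in enumerate(objs)]
    if format == "csv":
        cells: dict[str, dict[str, dict[tuple[int, int], float]]] = {}
        order: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sp = row["species_id"]
                if sp not in cells:
                    cells[sp] = {}
                    order.append(sp)
                cells[sp].setdefault(row["matrix"], {})[
                    (int(row["row"]), int(row["col"]))
                ] = float(row["value"])
        meta_path = path.with_name(path.stem + "_metadata.csv")
        meta: dict[str, dict] = {}
        with open(meta_path, newline="") as fh:
            for row in csv.DictReader(fh):
                meta[row["species_id"]] = row
        records = []
        for idx, sp in enumerate(order):
            mats = {}
            for name in ("T", "F", "A"):
                if name not in cells[sp]:
                    if name == "A":
                        mats["A"] = None
                        continue
                    raise StructuralError(f"record {idx} ({sp}): missing matrix '{name}'")
                entries = cells[sp][name]
                n = max(i for i, _ in entries) + 1
                M = np.zeros((n, n))
                for (i, j), val in entries.items():
                    M[i, j] = val
                mats[name] = M
            m = meta.get(sp)
            if m is None:
                raise StructuralError(f"record {idx} ({sp}): missing metadata row")
            records.append(
                ProjectionMatrixRecord(
                    species_id=sp,
                    listed=bool(int(m["listed"])),
                    T=mats["T"],
                    F=mats["F"],
                    A=mats["A"],
                    stages=m["stages"].split(";") if m["stages"] else None,
                    metadata=RecordMetadata(
                        treatment=m["treatment"],
                        periodicity_years=float(m["periodicity_years"]),
                        stage_criterion=m["stage_criterion"],
                        composition=m["composition"],
                        duration_years=float(m["duration_years"]),
                    ),
                )
            )
        return records
    raise ValueError(f"unknown format {format!r}")
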