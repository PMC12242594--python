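"""Facial phenotype descriptors and the ensemble cosine distance.

Each facial image is embedded as an ensemble of 12 descriptor vectors of
512 real components (one per member of a test-time-augmented model
ensemble).  Similarity between two images is the mean of the 12 per-slot
cosine distances,

    d(i, j) = (1/12) * sum_k (1 - cos(x_{i,k}, x_{j,k})),

and the distance between two image cohorts C1, C2 is the mean of d(i, j)
over all |C1|*|C2| cross pairs.  Both lie in [0, 2]; cosine distance makes
them invariant to positive rescaling of any descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohortError,
    InvalidDescriptorError,
    MissingImageError,
)

N_SLOTS = 12
N_DIM = 512

__all__ = [
    "N_SLOTS",
    "N_DIM",
    "FacialDescriptorSet",
    "DescriptorCollection",
    "CohortSpec",
    "image_distance",
    "cohort_distance",
    "rank_gallery",
    "load_descriptors",
    "save_descriptors",
]


def _validated_descriptors(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != (N_SLOTS, N_DIM):
        raise InvalidDescriptorError(
            f"descriptor ensemble must have shape ({N_SLOTS}, {N_DIM}), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidDescriptorError("descriptor components must be finite")
    norms = np.linalg.norm(arr, axis=1)
    if np.any(norms <= 0.0):
        bad = np.nonzero(norms <= 0.0)[0].tolist()
        raise InvalidDescriptorError(f"zero-norm descriptor vector(s) in slot(s) {bad}")
    return arr


@dataclass(frozen=True)
class FacialDescriptorSet:
    """One image's 12x512 descriptor ensemble with its identity labels."""

    image_id: str
    patient_id: str
    syndrome_id: str
    descriptors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", _validated_descriptors(self.descriptors))

    def unit_descriptors(self) -> np.ndarray:
        """Descriptors normalised to unit Euclidean norm per slot."""
        norms = np.linalg.norm(self.descriptors, axis=1, keepdims=True)
        return self.descriptors / norms


class DescriptorCollection:
    """Keyed set of :class:`FacialDescriptorSet` with patient/syndrome indices.

    Enforces unique image ids and label coherence (all images of a patient
    carry the same syndrome).  Caches a row-normalised flattened descriptor
    matrix so that all pairwise ensemble cosine distances reduce to one
    matrix product.
    """

    def __init__(self, items: Iterable[FacialDescriptorSet]) -> None:
        self._images: dict[str, FacialDescriptorSet] = {}
        for item in items:
            if item.image_id in self._images:
                raise InvalidDescriptorError(f"duplicate image_id {item.image_id!r}")
            self._images[item.image_id] = item
        patient_syndrome: dict[str, str] = {}
        for item in self._images.values():
            prev = patient_syndrome.setdefault(item.patient_id, item.syndrome_id)
            if prev != item.syndrome_id:
                raise InvalidDescriptorError(
                    f"patient {item.patient_id!r} carries conflicting syndrome labels "
                    f"{prev!r} and {item.syndrome_id!r}"
                )
        self._index: dict[str, int] = {iid: n for n, iid in enumerate(self._images)}
        self._unit_flat: np.ndarray | None = None
        self._dist: np.ndarray | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._images)

    def __iter__(self) -> Iterator[FacialDescriptorSet]:
        return iter(self._images.values())

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._images

    def __getitem__(self, image_id: str) -> FacialDescriptorSet:
        try:
            return self._images[image_id]
        except KeyError:
            raise MissingImageError(image_id) from None

    @property
    def image_ids(self) -> list[str]:
        return list(self._images)

    # -- derived indices ----------------------------------------------------
    @property
    def images_by_patient(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item in self._images.values():
            out.setdefault(item.patient_id, []).append(item.image_id)
        return out

    @property
    def patients_by_syndrome(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        seen: set[str] = set()
        for item in self._images.values():
            if item.patient_id not in seen:
                seen.add(item.patient_id)
                out.setdefault(item.syndrome_id, []).append(item.patient_id)
        return out

    @property
    def images_by_syndrome(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item in self._images.values():
            out.setdefault(item.syndrome_id, []).append(item.image_id)
        return out

    @property
    def syndrome_ids(self) -> list[str]:
        return list(self.images_by_syndrome)

    def subset(self, image_ids: Iterable[str]) -> "DescriptorCollection":
        return DescriptorCollection(self[iid] for iid in image_ids)

    # -- distance machinery -------------------------------------------------
    def unit_flat(self) -> np.ndarray:
        """(N, 12*512) matrix of per-slot unit-normalised descriptors."""
        if self._unit_flat is None:
            self._unit_flat = np.vstack(
                [item.unit_descriptors().ravel() for item in self._images.values()]
            )
        return self._unit_flat

    def distance_matrix(self) -> np.ndarray:
        """Full pairwise ensemble cosine distance matrix (symmetric, zero diagonal).

        With per-slot unit vectors, d(i,j) = 1 - <f_i, f_j>/12 where f is the
        flattened normalised ensemble; one matrix product yields all pairs.
        """
        if self._dist is None:
            flat = self.unit_flat()
            dist = 1.0 - (flat @ flat.T) / N_SLOTS
            np.fill_diagonal(dist, 0.0)
            self._dist = np.clip(dist, 0.0, 2.0)
        return self._dist

    def rows(self, image_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[iid] for iid in image_ids], dtype=np.intp)
        except KeyError as exc:
            raise MissingImageError(str(exc.args[0])) from None


@dataclass(frozen=True)
class CohortSpec:
    """A labelled, ordered set of image ids referencing a collection."""

    label: str
    image_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.image_ids) == 0:
            raise EmptyCohortError(f"cohort {self.label!r} is empty")
        object.__setattr__(self, "image_ids", tuple(self.image_ids))

    def validate(self, coll: DescriptorCollection) -> None:
        missing = [iid for iid in self.image_ids if iid not in coll]
        if missing:
            raise MissingImageError(f"cohort {self.label!r} references {missing}")

    def __len__(self) -> int:
        return len(self.image_ids)


def image_distance(a: FacialDescriptorSet, b: FacialDescriptorSet) -> float:
    """Mean of the 12 per-slot cosine distances between two images."""
    ua, ub = a.unit_descriptors(), b.unit_descriptors()
    cosines = np.einsum("kd,kd->k", ua, ub)
    return float(np.mean(1.0 - cosines))


def cohort_distance(
    c1: CohortSpec, c2: CohortSpec, coll: DescriptorCollection
) -> float:
    """Mean ensemble cosine distance over all cross pairs of two cohorts.

    Images present in both cohorts contribute their (zero) self-pairs; the
    formula is applied literally.
    """
    if len(c1) == 0 or len(c2) == 0:  # CohortSpec forbids this, belt and braces
        raise EmptyCohortError("cohort_distance requires nonempty cohorts")
    c1.validate(coll)
    c2.validate(coll)
    dist = coll.distance_matrix()
    block = dist[np.ix_(coll.rows(c1.image_ids), coll.rows(c2.image_ids))]
    return float(block.mean())


def rank_gallery(
    probe: str, gallery: Iterable[str], coll: DescriptorCollection
) -> list[tuple[str, float, int]]:
    """Rank gallery images by ascending ensemble distance to the probe.

    Ranks start at 1; exact distance ties are broken by lexicographic
    image id so the ordering is deterministic.
    """
    if probe not in coll:
        raise MissingImageError(probe)
    gallery = list(gallery)
    if not gallery:
        raise EmptyCohortError("gallery is empty")
    dist = coll.distance_matrix()
    prow = dist[coll.rows([probe])[0], coll.rows(gallery)]
    order = sorted(zip(gallery, prow), key=lambda t: (t[1], t[0]))
    return [(iid, float(d), rank) for rank, (iid, d) in enumerate(order, start=1)]


# -- tabular I/O -------------------------------------------------------------

_META_COLS = ["image_id", "patient_id", "syndrome_id"]
_VCOLS = [f"v{i:03d}" for i in range(1, N_DIM + 1)]


def save_descriptors(coll: DescriptorCollection, path, layout: str = "long") -> None:
    """Write a collection as tab-separated text.

    ``long``: one row per (image, slot): image_id, patient_id, syndrome_id,
    slot (1-12), v001..v512.  ``wide``: one row per image with the 6144
    floats of the flattened ensemble.
    """
    records = []
    if layout == "long":
        for item in coll:
            for k in range(N_SLOTS):
                records.append(
                    [item.image_id, item.patient_id, item.syndrome_id, k + 1]
                    + item.descriptors[k].tolist()
                )
        cols = _META_COLS + ["slot"] + _VCOLS
    elif layout == "wide":
        for item in coll:
            records.append(
                [item.image_id, item.patient_id, item.syndrome_id]
                + item.descriptors.ravel().tolist()
            )
        cols = _META_COLS + [
            f"v{k + 1:02d}_{i:03d}" for k in range(N_SLOTS) for i in range(1, N_DIM + 1)
        ]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    pd.DataFrame.from_records(records, columns=cols).to_csv(path, sep="\t", index=False)


def load_descriptors(path, layout: str = "long") -> DescriptorCollection:
    """Read a descriptor table written by :func:`save_descriptors`.

    Extra images never referenced by an analysis are kept: the collection
    may mix cohort and gallery images.
    """
    df = pd.read_csv(path, sep="\t")
    items: list[FacialDescriptorSet] = []
    if layout == "long":
        for image_id, grp in df.groupby("image_id", sort=False):
            slots = grp.sort_values("slot")
            if list(slots["slot"]) != list(range(1, N_SLOTS + 1)):
                raise InvalidDescriptorError(
                    f"image {image_id!r} must have exactly slots 1..{N_SLOTS}"
                )
            meta = slots.iloc[0]
            arr = slots.iloc[:, len(_META_COLS) + 1 :].to_numpy(dtype=np.float64)
            items.append(
                FacialDescriptorSet(
                    str(image_id), str(meta["patient_id"]), str(meta["syndrome_id"]), arr
                )
            )
    elif layout == "wide":
        for _, row in df.iterrows():
            arr = row.iloc[len(_META_COLS):].to_numpy(dtype=np.float64)
            items.append(
                FacialDescriptorSet(
                    str(row["image_id"]),
                    str(row["patient_id"]),
                    str(row["syndrome_id"]),
                    arr.reshape(N_SLOTS, N_DIM),
                )
            )
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return DescriptorCollection(items)
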