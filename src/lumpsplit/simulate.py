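"""Synthetic clinical-face-phenotype-space (CFPS) generator.

Emulates the hierarchical structure of real descriptor data — syndromes
containing patients containing images — as directional clusters on the
512-sphere.  Syndrome mean directions are drawn uniformly on the sphere
(nearly orthogonal in 512 dimensions, so distinct syndromes sit at an
ensemble cosine distance near 1); patient means scatter around their
syndrome mean with angular dispersion ``within_syndrome_spread``; the 12
descriptor slots of each image scatter around the patient mean with
``within_patient_spread`` plus an independent per-slot ``slot_jitter``.
Noise is tangent-space Gaussian followed by renormalisation, which is
adequate because only directions matter under the cosine metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import yaml

from .descriptors import N_DIM, N_SLOTS, DescriptorCollection, FacialDescriptorSet
from .errors import ConfigError

__all__ = ["CfpsSimConfig", "generate", "load_sim_config"]


@dataclass
class CfpsSimConfig:
    """Configuration for the synthetic descriptor generator.

    Defaults describe a well-separated benchmark collection: 40 syndromes
    of 3 patients with 2 images each, within-syndrome dispersion small
    relative to the near-unit separation of random syndrome directions.
    """

    n_syndromes: int = 40
    patients_per_syndrome: Union[int, Sequence[int]] = 3
    images_per_patient: Union[int, Sequence[int]] = 2
    within_syndrome_spread: float = 0.15
    within_patient_spread: float = 0.05
    slot_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syndromes < 1:
            raise ConfigError("n_syndromes must be >= 1")
        for name in ("within_syndrome_spread", "within_patient_spread", "slot_jitter"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("patients_per_syndrome", "images_per_patient"):
            val = getattr(self, name)
            counts = [val] if isinstance(val, int) else list(val)
            if any(int(c) < 1 for c in counts):
                raise ConfigError(f"{name} counts must be >= 1")

    def _per_syndrome_patients(self) -> list[int]:
        if isinstance(self.patients_per_syndrome, int):
            return [self.patients_per_syndrome] * self.n_syndromes
        counts = [int(c) for c in self.patients_per_syndrome]
        if len(counts) != self.n_syndromes:
            raise ConfigError(
                "patients_per_syndrome list length must equal n_syndromes"
            )
        return counts


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate(config: CfpsSimConfig) -> DescriptorCollection:
    """Draw a descriptor collection from the hierarchical directional model."""
    rng = np.random.default_rng(config.seed)
    items: list[FacialDescriptorSet] = []
    patients = config._per_syndrome_patients()
    img_spec = config.images_per_patient
    # spreads are angular dispersions (radians, small-angle): a Gaussian
    # perturbation of per-coordinate sd spread/sqrt(D) has expected norm
    # ~spread, tilting a unit mean direction by ~spread radians
    scale = 1.0 / np.sqrt(N_DIM)
    for s, n_pat in enumerate(patients):
        syndrome_id = f"S{s:03d}"
        s_mean = _unit(rng.standard_normal(N_DIM))
        for p in range(n_pat):
            patient_id = f"{syndrome_id}-P{p:02d}"
            p_mean = _unit(
                s_mean
                + config.within_syndrome_spread * scale * rng.standard_normal(N_DIM)
            )
            n_img = (
                int(img_spec)
                if isinstance(img_spec, int)
                else int(img_spec[int(rng.integers(len(img_spec)))])
            )
            for i in range(n_img):
                base = p_mean + config.within_patient_spread * scale * rng.standard_normal(N_DIM)
                slots = base[None, :] + config.slot_jitter * scale * rng.standard_normal(
                    (N_SLOTS, N_DIM)
                )
                items.append(
                    FacialDescriptorSet(
                        image_id=f"{patient_id}-I{i:02d}",
                        patient_id=patient_id,
                        syndrome_id=syndrome_id,
                        descriptors=_unit(slots),
                    )
                )
    return DescriptorCollection(items)


def load_sim_config(path) -> CfpsSimConfig:
    """Load a flat key-value YAML file into a :class:`CfpsSimConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("simulation config must be a mapping")
    known = set(CfpsSimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return CfpsSimConfig(**raw)
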