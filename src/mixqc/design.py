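"""Reciprocal mixture designs and sample manifests.

A reference-sample set is built from a small number of pure total-RNA
components (canonically liver, brain and placenta) combined into two
mixtures with swapped proportions (1:1:2 and 1:2:1 by volume).  Because
every miRNA signal in a mixture is a convex combination of the pure
component signals, the design fixes the largest between-mixture ratio any
miRNA can show, which is what makes the pair useful as a truth-bearing
process control.

This module holds the design matrix (the fractions ``phi``), the sample
manifest that maps measurement columns to roles, and the derived design
analytics (the log2 ratio bound, manifest sizes for the full and reduced
protocols).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MixtureDesign",
    "ManifestEntry",
    "SampleManifest",
    "make_default_design",
    "design_log2_bound",
    "build_manifest",
    "load_design",
    "save_design",
    "load_manifest",
    "save_manifest",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MixtureDesign:
    """Component identities and the fraction matrix defining each mixture.

    ``phi`` has one row per component and one column per mixture; column
    ``m`` holds the fraction of total RNA each component contributes to
    mixture ``m``.  Fractions are stored normalized: by-volume proportions
    such as 1:1:2 are converted to fractions at construction.
    """

    component_ids: tuple[str, ...]
    mixture_ids: tuple[str, ...]
    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        object.__setattr__(self, "mixture_ids", tuple(self.mixture_ids))
        if len(self.component_ids) < 2:
            raise ValueError("a mixture design needs at least 2 components")
        if len(self.mixture_ids) < 2:
            raise ValueError("a mixture design needs at least 2 mixtures")
        if phi.shape != (len(self.component_ids), len(self.mixture_ids)):
            raise ValueError(
                f"phi shape {phi.shape} does not match "
                f"{len(self.component_ids)} components x {len(self.mixture_ids)} mixtures"
            )
        if np.any(phi < 0):
            raise ValueError("mixture fractions must be nonnegative")
        colsums = phi.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _SUM_TOL):
            raise ValueError(f"each mixture's fractions must sum to 1; got {colsums}")
        if len(set(self.component_ids)) != len(self.component_ids):
            raise ValueError("duplicate component ids")
        if len(set(self.mixture_ids)) != len(self.mixture_ids):
            raise ValueError("duplicate mixture ids")

    @classmethod
    def from_proportions(
        cls,
        component_ids: Sequence[str],
        proportions: Mapping[str, Sequence[float]],
    ) -> "MixtureDesign":
        """Build a design from by-volume proportions (e.g. ``{"mix1": (1, 1, 2)}``).

        Each mixture's proportions are normalized to fractions summing to 1.
        """
        mixture_ids = tuple(proportions)
        cols = []
        for m in mixture_ids:
            p = np.asarray(proportions[m], dtype=float)
            if p.sum() <= 0:
                raise ValueError(f"proportions for {m!r} must have a positive sum")
            cols.append(p / p.sum())
        return cls(tuple(component_ids), mixture_ids, np.column_stack(cols))

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    @property
    def n_mixtures(self) -> int:
        return len(self.mixture_ids)

    def phi_for(self, mixture_id: str) -> np.ndarray:
        return self.phi[:, self.mixture_ids.index(mixture_id)]

    def invariant_components(self, atol: float = 1e-12) -> tuple[str, ...]:
        """Components whose fraction is identical in every mixture.

        Signals drawn only from these components are predicted to show no
        between-mixture difference, which is what makes them designed true
        negatives.
        """
        same = np.all(np.abs(self.phi - self.phi[:, [0]]) <= atol, axis=1)
        return tuple(c for c, s in zip(self.component_ids, same) if s)

    def to_dict(self) -> dict:
        return {
            "components": list(self.component_ids),
            "mixtures": {
                m: [float(v) for v in self.phi[:, j]]
                for j, m in enumerate(self.mixture_ids)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureDesign":
        return cls.from_proportions(d["components"], d["mixtures"])


def make_default_design() -> MixtureDesign:
    """The canonical 3-component, 2-mixture design.

    Liver, brain and placenta combined by volume as 1:1:2 (Mix1) and
    1:2:1 (Mix2), i.e. fractions (0.25, 0.25, 0.5) and (0.25, 0.5, 0.25)
    in (L, B, P) order.  Liver is the invariant component.
    """
    return MixtureDesign.from_proportions(
        ("liver", "brain", "placenta"),
        {"mix1": (1, 1, 2), "mix2": (1, 2, 1)},
    )


def design_log2_bound(design: MixtureDesign) -> float:
    """Largest achievable |log2(Mix1/Mix2)| for any signal under linear mixing.

    For nonnegative per-component signals the predicted mixture ratio is a
    ratio of convex combinations, so it is extremized by putting all signal
    on a single component; the bound is ``max_c |log2(phi_c1 / phi_c2)|``.
    Returns ``inf`` when some component is present in one mixture only.
    """
    if design.n_mixtures != 2:
        raise ValueError("log2 bound is defined for exactly 2 mixtures")
    p1, p2 = design.phi[:, 0], design.phi[:, 1]
    best = 0.0
    for a, b in zip(p1, p2):
        if a == 0.0 and b == 0.0:
            continue
        if a == 0.0 or b == 0.0:
            return math.inf
        best = max(best, abs(math.log2(a / b)))
    return best


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    role: str  # "pure:<component>" or "mix:<mixture>"
    replicate_index: int
    round_id: str = "round1"

    def __post_init__(self) -> None:
        kind, _, target = self.role.partition(":")
        if kind not in ("pure", "mix") or not target:
            raise ValueError(
                f"role must be 'pure:<component>' or 'mix:<mixture>', got {self.role!r}"
            )
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")

    @property
    def kind(self) -> str:
        return self.role.partition(":")[0]

    @property
    def target(self) -> str:
        return self.role.partition(":")[2]


@dataclass(frozen=True)
class SampleManifest:
    """Maps sample (column) ids to their role in the mixture design."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def samples_for_role(self, role: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.role == role]

    def pure_components(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.kind == "pure" and e.target not in seen:
                seen.append(e.target)
        return seen

    def mixtures(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.kind == "mix" and e.target not in seen:
                seen.append(e.target)
        return seen

    def subset(self, sample_ids: Iterable[str]) -> "SampleManifest":
        keep = set(sample_ids)
        return SampleManifest(tuple(e for e in self.entries if e.sample_id in keep))

    def replicate(self, replicate_index: int) -> "SampleManifest":
        return SampleManifest(
            tuple(e for e in self.entries if e.replicate_index == replicate_index)
        )

    def validate_against(self, design: MixtureDesign) -> None:
        """Check every role references a component or mixture of the design."""
        for e in self.entries:
            pool = design.component_ids if e.kind == "pure" else design.mixture_ids
            if e.target not in pool:
                raise ValueError(
                    f"manifest role {e.role!r} references unknown "
                    f"{'component' if e.kind == 'pure' else 'mixture'} {e.target!r}"
                )

    def to_dict(self) -> dict:
        return {
            "samples": [
                {
                    "sample_id": e.sample_id,
                    "role": e.role,
                    "replicate_index": e.replicate_index,
                    "round_id": e.round_id,
                }
                for e in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleManifest":
        return cls(
            tuple(
                ManifestEntry(
                    sample_id=s["sample_id"],
                    role=s["role"],
                    replicate_index=int(s.get("replicate_index", 1)),
                    round_id=str(s.get("round_id", "round1")),
                )
                for s in d["samples"]
            )
        )


def build_manifest(
    design: MixtureDesign,
    n_replicates: int,
    mode: Literal["full", "mixtures_only"] = "full",
    round_id: str = "round1",
) -> SampleManifest:
    """Enumerate the samples a round of the protocol requires.

    ``full`` lists every pure component and every mixture (the 15-sample
    protocol for the default design at 3 replicates); ``mixtures_only``
    lists just the mixtures (the reduced 6-sample protocol used once a
    pure-component baseline is banked).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    roles: list[str] = []
    if mode == "full":
        roles += [f"pure:{c}" for c in design.component_ids]
    elif mode != "mixtures_only":
        raise ValueError(f"unknown mode {mode!r}")
    roles += [f"mix:{m}" for m in design.mixture_ids]
    entries = [
        ManifestEntry(
            sample_id=f"{role.partition(':')[2]}_rep{r}",
            role=role,
            replicate_index=r,
            round_id=round_id,
        )
        for role in roles
        for r in range(1, n_replicates + 1)
    ]
    return SampleManifest(tuple(entries))


def save_design(design: MixtureDesign, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(design.to_dict(), sort_keys=False))


def load_design(path: str | Path) -> MixtureDesign:
    return MixtureDesign.from_dict(yaml.safe_load(Path(path).read_text()))


def save_manifest(manifest: SampleManifest, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=False))


def load_manifest(path: str | Path) -> SampleManifest:
    return SampleManifest.from_dict(yaml.safe_load(Path(path).read_text()))
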