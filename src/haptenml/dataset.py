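"""Hapten-level training sets from substance-level sensitizer labels.

Patch-test prevalence data label *substances*, but many baseline-series
substances are mixes of 2–4 component haptens.  Labels are propagated to
the hapten level with the following rules:

* a single-hapten substance passes its 0/1 label to its hapten;
* a mix labeled 0 (non-sensitizer) labels every component 0 — if the mix
  does not sensitize, none of its components can;
* a mix labeled 1 contributes nothing: the signal cannot be attributed to
  any particular component without component-level epidemiology;
* non-organic substances (cobalt, chromium salts) contribute nothing —
  the descriptor providers cannot characterize them on the same footing
  as organic molecules;
* substances explicitly excluded for an endpoint contribute nothing.

The module also aligns hapten records with a descriptor matrix into a
:class:`TrainingSet` and round-trips learning sets through ARFF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from haptenml.arff import ArffParseError, read_arff as _read_arff_file, write_arff as _write_arff_file
from haptenml.featurize import DescriptorMatrix

__all__ = [
    "EXCLUDED",
    "Excluded",
    "HaptenIdentity",
    "SubstanceEntry",
    "HaptenRecord",
    "TrainingSet",
    "NAME_ALIASES",
    "normalize_name",
    "propagate_labels",
    "build_training_set",
    "read_arff",
    "write_arff",
    "ArffParseError",
]


class Excluded:
    """Sentinel label for a substance excluded from an endpoint's model."""

    _instance = None

    def __new__(cls) -> "Excluded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EXCLUDED"


EXCLUDED = Excluded()

#: Spelling variants used across the source tables, mapped to a canonical
#: normalized form.  Matching is by exact normalized name otherwise.
NAME_ALIASES: Dict[str, str] = {
    "neomycin": "neomycin sulfate",
    "sorbitan sesquilate": "sorbitan sesquioleate",
    "hydroxyisohexyl 3-cyclohexene carboxaldehyde (hicc, lyral)": (
        "hydroxyisohexyl 3-cyclohexene carboxaldehyde"
    ),
    "hydroxyisohexyl 3-cyclohexene carboxaldehyde (hicc)-lyral": (
        "hydroxyisohexyl 3-cyclohexene carboxaldehyde"
    ),
    "methylchloroisothiazolinone": "methylchloroisothiazolinone (mci)",
    "methylisothiazolinone": "methylisothiazolinone (mi)",
    "diazolidynyl urea": "diazolidinyl urea",
    "imidazolidynyl urea": "imidazolidinyl urea",
}


def normalize_name(name: str) -> str:
    """Case-fold, collapse whitespace, and resolve known aliases."""
    norm = re.sub(r"\s+", " ", name.strip()).casefold()
    norm = norm.replace("’", "'").replace("–", "-").replace("—", "-")
    return NAME_ALIASES.get(norm, norm)


@dataclass(frozen=True)
class HaptenIdentity:
    """Chemical identity of one component hapten."""

    name: str
    cas: str = "n/a"
    smiles: str = ""
    representative: bool = False  # UVCB substance with a stand-in structure


@dataclass
class SubstanceEntry:
    """One patch-test substance with endpoint labels and components."""

    substance_name: str
    components: List[HaptenIdentity]
    label_eor: Union[int, Excluded] = EXCLUDED
    label_ear: Union[int, Excluded] = EXCLUDED
    organic: bool = True

    def label_for(self, endpoint: str) -> Union[int, Excluded]:
        if endpoint == "eOR":
            return self.label_eor
        if endpoint == "eAR":
            return self.label_ear
        raise ValueError(f"unknown endpoint {endpoint!r}")


@dataclass(frozen=True)
class HaptenRecord:
    """A single hapten with its propagated endpoint label."""

    hapten_name: str
    cas: str
    smiles: str
    label: int
    endpoint: str
    representative: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if self.endpoint not in ("eOR", "eAR"):
            raise ValueError(f"endpoint must be eOR|eAR, got {self.endpoint!r}")


@dataclass
class TrainingSet:
    """Aligned hapten records, descriptor matrix and label vector."""

    endpoint: str
    records: List[HaptenRecord]
    descriptor_names: List[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        names = [normalize_name(r.hapten_name) for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate hapten names: {dupes}")
        if self.X.shape != (len(self.records), len(self.descriptor_names)):
            raise ValueError("descriptor matrix shape mismatch")
        if self.y.shape != (len(self.records),):
            raise ValueError("label vector shape mismatch")

    def __len__(self) -> int:
        return len(self.records)

    def subset_features(self, names: Sequence[str]) -> "TrainingSet":
        """Restrict to the named descriptor columns, order as given."""
        index = {n: i for i, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown descriptors: {missing}")
        cols = [index[n] for n in names]
        return TrainingSet(
            endpoint=self.endpoint,
            records=list(self.records),
            descriptor_names=list(names),
            X=self.X[:, cols].copy(),
            y=self.y.copy(),
        )


def propagate_labels(
    substances: Sequence[SubstanceEntry], endpoint: str
) -> List[HaptenRecord]:
    """Expand substance labels to hapten records for one endpoint.

    See the module docstring for the propagation rules.  Raises
    ``ValueError`` for a substance with no components (malformed input).
    """
    if endpoint not in ("eOR", "eAR"):
        raise ValueError(f"endpoint must be eOR|eAR, got {endpoint!r}")
    out: List[HaptenRecord] = []
    for sub in substances:
        if not sub.components:
            raise ValueError(f"substance {sub.substance_name!r} has no components")
        label = sub.label_for(endpoint)
        if isinstance(label, Excluded):
            continue
        if label not in (0, 1):
            raise ValueError(
                f"substance {sub.substance_name!r}: label must be 0/1 or EXCLUDED"
            )
        if not sub.organic:
            continue
        if len(sub.components) > 1 and label == 1:
            # cannot attribute the sensitizing signal to a single component
            continue
        for comp in sub.components:
            out.append(
                HaptenRecord(
                    hapten_name=comp.name,
                    cas=comp.cas,
                    smiles=comp.smiles,
                    label=int(label),
                    endpoint=endpoint,
                    representative=comp.representative,
                )
            )
    return out


def build_training_set(
    haptens: Sequence[HaptenRecord], descriptors: DescriptorMatrix
) -> TrainingSet:
    """Align hapten records with descriptor rows (matched by name).

    Raises
    ------
    ValueError
        If the hapten list is empty, contains duplicates, or any hapten
        lacks a descriptor row / has missing descriptor values — the
        error message names every offender.
    """
    if not haptens:
        raise ValueError("empty hapten list")
    endpoints = {h.endpoint for h in haptens}
    if len(endpoints) != 1:
        raise ValueError(f"mixed endpoints in hapten list: {sorted(endpoints)}")
    row_index = {normalize_name(r): i for i, r in enumerate(descriptors.row_ids)}
    unmatched = [h.hapten_name for h in haptens if normalize_name(h.hapten_name) not in row_index]
    if unmatched:
        raise ValueError(f"haptens without descriptor rows: {unmatched}")
    rows = [row_index[normalize_name(h.hapten_name)] for h in haptens]
    X = descriptors.values[rows, :].astype(float)
    incomplete = [
        haptens[i].hapten_name for i in range(len(haptens)) if np.isnan(X[i]).any()
    ]
    if incomplete:
        raise ValueError(f"haptens with missing descriptor values: {incomplete}")
    y = np.array([h.label for h in haptens], dtype=int)
    return TrainingSet(
        endpoint=next(iter(endpoints)),
        records=list(haptens),
        descriptor_names=list(descriptors.descriptor_names),
        X=X,
        y=y,
    )


def read_arff(path: Union[str, Path]) -> Tuple[DescriptorMatrix, Optional[np.ndarray]]:
    """Read a WEKA-dialect ARFF learning set.

    Returns the descriptor matrix (row ids are synthesized as ``r0001``,
    ``r0002``, … since ARFF carries no instance names) and the class
    vector, or ``None`` when the file has no nominal class attribute.
    """
    data = _read_arff_file(path)
    n = data.values.shape[0]
    matrix = DescriptorMatrix(
        row_ids=[f"r{i + 1:04d}" for i in range(n)],
        descriptor_names=list(data.attribute_names),
        values=data.values,
        provider_id=f"arff:{data.relation}",
    )
    return matrix, data.class_values


def write_arff(
    matrix: DescriptorMatrix,
    path: Union[str, Path],
    labels: Optional[Sequence[int]] = None,
    relation: str = "haptenml",
) -> None:
    """Write a descriptor matrix (plus optional {0,1} labels) as ARFF."""
    _write_arff_file(
        path,
        relation=relation,
        attribute_names=matrix.descriptor_names,
        values=matrix.values,
        class_values=labels,
    )
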