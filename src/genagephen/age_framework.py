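"""Evolutionary age framework: branches, epochs, branch times, and the
sparse-branch merging rule.

Genes are stratified into seven ancestral branches (br0, the Euteleostomi
node or older, through br6, the youngest human-lineage node), grouped into
four coarse epochs: Euteleostomi, Tetrapoda, Amniota and Eutheria.  Branch
origin ages (My before present) are configuration with TimeTree-derived
defaults; no time value is hard-coded in analysis logic.  Branches with
fewer genes than a floor (default 100) are merged into their adjacent older
branch, cascading oldward until every retained branch meets the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

EPOCHS: list[str] = ["Euteleostomi", "Tetrapoda", "Amniota", "Eutheria"]

#: Default merge floor: branches with fewer genes are merged oldward.
DEFAULT_MERGE_FLOOR = 100


@dataclass(frozen=True)
class BranchDefinition:
    """One ancestral branch: label, clade name, origin age (My), epoch."""

    label: str
    name: str
    origin_age: float
    epoch: str


#: TimeTree-derived default branch set, oldest to youngest.
DEFAULT_BRANCHES: list[BranchDefinition] = [
    BranchDefinition("br0", "Euteleostomi", 435.0, "Euteleostomi"),
    BranchDefinition("br1", "Tetrapoda", 352.0, "Tetrapoda"),
    BranchDefinition("br2", "Amniota", 319.0, "Amniota"),
    BranchDefinition("br3", "Eutheria", 105.0, "Eutheria"),
    BranchDefinition("br4", "Euarchontoglires", 90.0, "Eutheria"),
    BranchDefinition("br5", "Primates", 74.0, "Eutheria"),
    BranchDefinition("br6", "Catarrhini", 29.0, "Eutheria"),
]


class ConfigError(ValueError):
    """Invalid branch/epoch/time configuration."""


class AgeFramework:
    """An ordered (old to young) set of branches with epochs and times.

    Parameters
    ----------
    branches
        Branch definitions ordered oldest first, with strictly decreasing
        origin ages and epochs drawn from the configured epoch list.
    """

    def __init__(self, branches: list[BranchDefinition] | None = None,
                 epochs: list[str] | None = None):
        self.branches = list(branches) if branches is not None else list(DEFAULT_BRANCHES)
        self.epochs = list(epochs) if epochs is not None else list(EPOCHS)
        self._validate()
        self._by_label = {b.label: b for b in self.branches}

    def _validate(self) -> None:
        if not self.branches:
            raise ConfigError("framework needs at least one branch")
        ages = [b.origin_age for b in self.branches]
        if any(a <= 0 for a in ages):
            raise ConfigError("origin ages must be positive")
        if any(a1 <= a2 for a1, a2 in zip(ages, ages[1:])):
            raise ConfigError(
                "origin ages must be strictly decreasing from oldest to youngest")
        unknown = {b.epoch for b in self.branches} - set(self.epochs)
        if unknown:
            raise ConfigError(f"unknown epoch labels: {sorted(unknown)}")
        seen: set[str] = set()
        for b in self.branches:
            if b.label in seen:
                raise ConfigError(f"duplicate branch label {b.label!r}")
            seen.add(b.label)
        # epochs must label contiguous runs of branches (they partition the
        # ordered branch list into age stages)
        run = [b.epoch for b in self.branches]
        collapsed = [e for i, e in enumerate(run) if i == 0 or run[i - 1] != e]
        if len(collapsed) != len(set(collapsed)):
            raise ConfigError("epochs must group contiguous branches")

    # -- lookups -----------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.branches]

    def branch(self, label: str) -> BranchDefinition:
        try:
            return self._by_label[label]
        except KeyError:
            raise ConfigError(f"unknown branch {label!r}") from None

    def origin_age(self, label: str) -> float:
        return self.branch(label).origin_age

    def assign_epoch(self, label: str) -> str:
        """Epoch of a branch; total function on configured branches."""
        return self.branch(label).epoch

    def epoch_branches(self, epoch: str) -> list[str]:
        return [b.label for b in self.branches if b.epoch == epoch]

    def branch_duration(self, label: str) -> float:
        """Branch time span T_i in My.

        T_i = origin_age(branch) - origin_age(next younger branch); the
        youngest branch spans to the present (0 My).
        """
        idx = self.labels.index(self.branch(label).label)
        younger = self.branches[idx + 1].origin_age if idx + 1 < len(self.branches) else 0.0
        return self.branch(label).origin_age - younger

    def durations(self) -> pd.Series:
        return pd.Series({b.label: self.branch_duration(b.label) for b in self.branches},
                         name="T_my")

    def t_since_youngest(self, label: str, unit_my: float = 100.0) -> float:
        """Evolutionary time coordinate for growth modelling.

        Measured from the youngest branch's origin, in ``unit_my``-My units
        (default 100 My), so the youngest branch sits at t = 0 and older
        branches at increasing t.
        """
        youngest = self.branches[-1].origin_age
        return (self.branch(label).origin_age - youngest) / unit_my

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": self.labels,
                "name": [b.name for b in self.branches],
                "origin_age_my": [b.origin_age for b in self.branches],
                "epoch": [b.epoch for b in self.branches],
                "T_my": [self.branch_duration(b.label) for b in self.branches],
            }
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "AgeFramework":
        """Load a framework from a YAML file.

        Expected shape::

            epochs: [Euteleostomi, Tetrapoda, Amniota, Eutheria]
            branches:
              - {label: br0, name: Euteleostomi, origin_age: 435, epoch: Euteleostomi}
              ...
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            branches = [
                BranchDefinition(str(b["label"]), str(b.get("name", b["label"])),
                                 float(b["origin_age"]), str(b["epoch"]))
                for b in raw["branches"]
            ]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed branch config: {exc}") from exc
        return cls(branches, raw.get("epochs"))

    def to_yaml(self, path) -> None:
        payload = {
            "epochs": self.epochs,
            "branches": [
                {"label": b.label, "name": b.name,
                 "origin_age": b.origin_age, "epoch": b.epoch}
                for b in self.branches
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def merge_sparse_branches(
    assignments: pd.Series,
    framework: AgeFramework,
    floor: int = DEFAULT_MERGE_FLOOR,
) -> tuple[pd.Series, dict[str, str]]:
    """Merge branches with fewer than ``floor`` genes into the adjacent
    older branch, cascading oldward until every retained branch meets the
    floor.

    Parameters
    ----------
    assignments
        Per-gene raw branch labels (values must be framework branches).
    framework
        Branch order, oldest first.
    floor
        Strict minimum retained-branch gene count (a branch with exactly
        ``floor`` genes is retained).

    Returns
    -------
    (merged, mapping)
        ``merged`` is the relabelled series; ``mapping`` maps every input
        branch label to its retained label.  Idempotent: re-applying the
        merge to its own output changes nothing.

    Raises
    ------
    ConfigError
        If an assignment uses an unknown branch, or the oldest branch ends
        below the floor (it has no older neighbour to merge into).
    """
    labels = framework.labels
    unknown = set(assignments.unique()) - set(labels)
    if unknown:
        raise ConfigError(f"assignments use unknown branches: {sorted(unknown)}")
    counts = assignments.value_counts().reindex(labels, fill_value=0)

    merged_counts = counts.astype(int).to_dict()
    target = {lab: lab for lab in labels}
    # youngest-first pass: a sparse branch hands its (possibly already
    # augmented) count to the adjacent older branch
    for i in range(len(labels) - 1, 0, -1):
        lab = labels[i]
        if 0 < merged_counts[lab] < floor:
            older = labels[i - 1]
            merged_counts[older] += merged_counts[lab]
            merged_counts[lab] = 0
            target[lab] = older
    # resolve chains (br6 -> br5 -> br4 becomes br6 -> br4)
    for lab in labels:
        t = lab
        while target[t] != t:
            t = target[t]
        target[lab] = t
    oldest = labels[0]
    if 0 < merged_counts[oldest] < floor:
        raise ConfigError(
            f"oldest branch {oldest!r} has {merged_counts[oldest]} genes "
            f"(< {floor}) and no older neighbour to merge into")
    merged = assignments.map(target)
    merged.name = assignments.name
    return merged, target
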