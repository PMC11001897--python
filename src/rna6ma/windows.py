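"""Labeled 41-nt RNA windows: reading, validation, generation, splitting.

A sample is a fixed-length window R(-L) ... R(-1) A R(+1) ... R(+L) with
L = 20: 41 nucleotides with the putatively methylated adenosine at the
center. Class 1 marks a 6mA site, class 0 a non-site. DNA-alphabet input
is coerced T->U before validation so either alphabet loads transparently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
#: window length 2L+1 with L=20
WINDOW_LENGTH = 41
#: 0-based index of the central adenosine (position 21 when 1-based)
CENTER_INDEX = 20

_BASE_TO_COL = {b: i for i, b in enumerate(ALPHABET)}


class WindowError(ValueError):
    """A sequence violates the 41-nt central-A window contract."""


@dataclass(frozen=True)
class RnaWindow:
    """One 41-nt sample with a central adenosine and a binary 6mA label."""

    id: str
    sequence: str
    label: int
    species: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        validate_sequence(self.sequence)
        if self.label not in (0, 1):
            raise WindowError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def reversed(self) -> "RnaWindow":
        """The same sample read 3'->5'; central A is preserved by symmetry."""
        return replace(self, sequence=self.sequence[::-1])


def normalize_sequence(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def validate_sequence(seq: str) -> None:
    """Raise :class:`WindowError` unless ``seq`` is a valid window."""
    if len(seq) != WINDOW_LENGTH:
        raise WindowError(
            f"window must be {WINDOW_LENGTH} nt, got {len(seq)}"
        )
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise WindowError(f"ambiguous base: {sorted(bad)}")
    if seq[CENTER_INDEX] != "A":
        raise WindowError(
            f"central base (position {CENTER_INDEX + 1}) must be A, "
            f"got {seq[CENTER_INDEX]!r}"
        )


@dataclass
class WindowDataset:
    """An ordered collection of windows with a dataset label."""

    windows: list[RnaWindow] = field(default_factory=list)
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> RnaWindow:
        return self.windows[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {c: int((labels == c).sum()) for c in (0, 1)}

    def subset(self, indices, name: str | None = None) -> "WindowDataset":
        return WindowDataset(
            [self.windows[i] for i in indices], name or self.name
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [w.id for w in self.windows],
                "sequence": [w.sequence for w in self.windows],
                "label": [w.label for w in self.windows],
                "species": [w.species for w in self.windows],
            }
        )


def read_fasta(path, label: int, species: str | None = None) -> WindowDataset:
    """Load windows from a plain FASTA file, all carrying ``label``.

    Records failing the window contract are skipped with a logged reason;
    an empty valid set is a fatal error naming the rejection count.
    """
    windows: list[RnaWindow] = []
    rejected = 0
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            windows.append(
                RnaWindow(record.id, str(record.seq), label, species)
            )
        except WindowError as exc:
            rejected += 1
            logger.warning("skipping record %s: %s", record.id, exc)
    if not windows:
        raise ValueError(
            f"no valid windows in {path} ({rejected} records rejected)"
        )
    if rejected:
        logger.info("read %d windows from %s (%d rejected)",
                    len(windows), path, rejected)
    return WindowDataset(windows, name=str(path))


def read_tsv(path) -> WindowDataset:
    """Load windows from a TSV with columns id, sequence, label[, species]."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    missing = {"id", "sequence", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"TSV missing columns: {sorted(missing)}")
    windows: list[RnaWindow] = []
    rejected = 0
    for row in df.itertuples(index=False):
        species = getattr(row, "species", None)
        if species is not None and pd.isna(species):
            species = None
        try:
            windows.append(
                RnaWindow(row.id, row.sequence, int(row.label), species)
            )
        except WindowError as exc:
            rejected += 1
            logger.warning("skipping record %s: %s", row.id, exc)
    if not windows:
        raise ValueError(
            f"no valid windows in {path} ({rejected} records rejected)"
        )
    return WindowDataset(windows, name=str(path))


def write_tsv(ds: WindowDataset, path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False)


def write_fasta(ds: WindowDataset, path) -> None:
    with open(path, "w") as fh:
        for w in ds:
            fh.write(f">{w.id} label={w.label}\n{w.sequence}\n")


def deduplicate(ds: WindowDataset) -> WindowDataset:
    """Drop exact (sequence, label) duplicates, keeping first occurrences.

    Sequences appearing under both labels are kept (distinct pairs) but a
    cross-label conflict warning is logged for each.
    """
    seen: set[tuple[str, int]] = set()
    by_seq: dict[str, set[int]] = {}
    kept: list[RnaWindow] = []
    for w in ds:
        key = (w.sequence, w.label)
        if key in seen:
            continue
        seen.add(key)
        kept.append(w)
        by_seq.setdefault(w.sequence, set()).add(w.label)
    removed = len(ds) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d exact duplicates", removed)
    for seq, labels in by_seq.items():
        if len(labels) > 1:
            logger.warning(
                "cross-label conflict: sequence %s... appears with both labels",
                seq[:12],
            )
    return WindowDataset(kept, name=ds.name)


def uniform_profile() -> np.ndarray:
    """Background per-position base probabilities: 1/4 each, center forced A."""
    profile = np.full((WINDOW_LENGTH, 4), 0.25)
    profile[CENTER_INDEX] = [1.0, 0.0, 0.0, 0.0]
    return profile


def planted_profile(strength: float = 0.9) -> np.ndarray:
    """Positional-composition bias separating the positive class.

    Emulates a sequence context around the methylated adenosine: a fixed
    periodic GGACU-like consensus phased so the center lands on its A.
    At each non-center position the consensus base has probability
    ``(1-strength)/4 + strength``; ``strength=0`` is the uniform
    background, ``strength=1`` a deterministic (perfectly separable)
    motif.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    motif = "GGACU"
    profile = np.full((WINDOW_LENGTH, 4), (1.0 - strength) / 4.0)
    for i in range(WINDOW_LENGTH):
        base = motif[(i + 2) % len(motif)]
        profile[i, _BASE_TO_COL[base]] += strength
    profile[CENTER_INDEX] = [1.0, 0.0, 0.0, 0.0]
    return profile


def generate_synthetic(
    n_pos: int,
    n_neg: int,
    bias: np.ndarray | None = None,
    seed: int = 0,
) -> WindowDataset:
    """Simulate labeled windows: positives from ``bias``, negatives uniform.

    ``bias`` is a (41, 4) row-stochastic matrix over (A, C, G, U); row 21
    (the center) must put all mass on A. Defaults to
    ``planted_profile()``. Deterministic given ``seed``.
    """
    if bias is None:
        bias = planted_profile()
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (WINDOW_LENGTH, 4):
        raise ValueError(f"bias must have shape ({WINDOW_LENGTH}, 4)")
    if not np.allclose(bias.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each bias row must sum to 1 within 1e-9")
    bias = bias.copy()
    bias[CENTER_INDEX] = [1.0, 0.0, 0.0, 0.0]

    rng = np.random.default_rng(seed)
    windows: list[RnaWindow] = []

    def draw(profile: np.ndarray, label: int, n: int, prefix: str) -> None:
        if n == 0:
            return
        # inverse-CDF sampling, vectorized over windows and positions
        cum = profile.cumsum(axis=1)
        u = rng.random((n, WINDOW_LENGTH))
        cols = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        bases = np.array(list(ALPHABET))
        for i in range(n):
            seq = "".join(bases[cols[i]])
            windows.append(
                RnaWindow(f"{prefix}{i}", seq, label, species="synthetic")
            )

    draw(bias, 1, n_pos, "pos")
    draw(uniform_profile(), 0, n_neg, "neg")
    return WindowDataset(windows, name=f"synthetic(seed={seed})")


def stratified_split(
    ds: WindowDataset, test_fraction: float, seed: int = 0
) -> tuple[WindowDataset, WindowDataset]:
    """Deterministic stratified partition into train and test sets."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    counts = ds.class_counts()
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 members, got {counts}")
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=ds.labels,
        random_state=seed,
    )
    return (
        ds.subset(sorted(train_idx), name=f"{ds.name}/train"),
        ds.subset(sorted(test_idx), name=f"{ds.name}/test"),
    )
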