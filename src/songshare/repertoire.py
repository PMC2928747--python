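"""Syllable and syllable-sequence repertoires and the repertoire-similarity (RS) coefficient.

A repertoire is the set of distinct syllable types — or of distinct contiguous
syllable n-grams with n in [n_min, n_max] pooled into one set — produced by an
individual across its songs.  Sharing between two individuals is quantified by

    RS = Z / ((X + Y) - Z)

where X and Y are the two repertoire sizes and Z the shared count;
algebraically RS is the Jaccard index of the two sets and ranges from 0
(nothing shared) to 1 (identical repertoires).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEQ_N_MIN = 3
SEQ_N_MAX = 10

#: Partner categories: adjacent neighbour, distant neighbour, stranger.
CATEGORIES = ("aN", "dN", "S")


@dataclass(frozen=True)
class Repertoire:
    """A set of syllable labels (kind='syllable') or of ordered label tuples
    with lengths in [n_min, n_max] (kind='sequence') for one individual."""

    individual_id: str
    kind: str
    items: frozenset

    @property
    def size(self) -> int:
        """Repertoire size — the X (or Y) of the RS formula."""
        return len(self.items)


@dataclass(frozen=True)
class RSValue:
    pair: tuple[str, str]
    Z: int
    RS: float


def _songs(transcripts) -> list[list[str]]:
    """Normalize input to a list of syllable-label lists, one per song.

    Accepts a tidy transcript DataFrame (columns song_id, position, syllable)
    restricted to one individual, or an iterable of label sequences.
    """
    if isinstance(transcripts, pd.DataFrame):
        if transcripts["individual_id"].nunique() > 1:
            raise ValueError("transcripts span multiple individuals")
        out = []
        for _, song in transcripts.groupby("song_id", sort=True):
            out.append(song.sort_values("position")["syllable"].tolist())
        return out
    return [list(s) for s in transcripts]


def syllable_repertoire(transcripts, individual_id: str = "") -> Repertoire:
    """Distinct syllable types across all of one individual's songs."""
    songs = _songs(transcripts)
    if not songs:
        raise ValueError("at least one transcript is required")
    items = set()
    for song in songs:
        for lab in song:
            if not isinstance(lab, str) or not lab:
                raise ValueError("syllable labels must be non-empty strings")
            items.add(lab)
    if isinstance(transcripts, pd.DataFrame) and not individual_id:
        individual_id = str(transcripts["individual_id"].iloc[0])
    return Repertoire(individual_id, "syllable", frozenset(items))


def sequence_repertoire(
    transcripts,
    n_min: int = SEQ_N_MIN,
    n_max: int = SEQ_N_MAX,
    individual_id: str = "",
) -> Repertoire:
    """Distinct contiguous n-grams, pooled over every n in [n_min, n_max].

    Windows use stride 1 and never span song boundaries; songs shorter than
    n_min contribute nothing.
    """
    if not 1 <= n_min <= n_max:
        raise ValueError(f"need 1 <= n_min <= n_max, got [{n_min}, {n_max}]")
    songs = _songs(transcripts)
    if not songs:
        raise ValueError("at least one transcript is required")
    items = set()
    for song in songs:
        L = len(song)
        for n in range(n_min, min(n_max, L) + 1):
            for i in range(L - n + 1):
                items.add(tuple(song[i : i + n]))
    if isinstance(transcripts, pd.DataFrame) and not individual_id:
        individual_id = str(transcripts["individual_id"].iloc[0])
    return Repertoire(individual_id, "sequence", frozenset(items))


def repertoire_similarity(a: Repertoire, b: Repertoire) -> RSValue:
    """RS = Z/((X+Y)-Z) between two repertoires of the same kind."""
    if a.kind != b.kind:
        raise ValueError(f"repertoire kinds differ: {a.kind!r} vs {b.kind!r}")
    if not a.items and not b.items:
        raise ValueError(
            "RS of two empty repertoires is undefined (0/0); refusing to guess"
        )
    z = len(a.items & b.items)
    rs = z / ((a.size + b.size) - z)
    return RSValue((a.individual_id, b.individual_id), z, rs)


def pairwise_rs_matrix(repertoires: Iterable[Repertoire]) -> pd.DataFrame:
    """Symmetric RS matrix over a collection of same-kind repertoires."""
    reps = list(repertoires)
    ids = [r.individual_id for r in reps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual ids: {dupes}")
    kinds = {r.kind for r in reps}
    if len(kinds) > 1:
        raise ValueError(f"mixed repertoire kinds: {sorted(kinds)}")
    n = len(reps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = repertoire_similarity(reps[i], reps[j]).RS
    return pd.DataFrame(m, index=ids, columns=ids)


def repertoires_from_transcripts(
    transcripts: pd.DataFrame,
    kind: str = "syllable",
    n_min: int = SEQ_N_MIN,
    n_max: int = SEQ_N_MAX,
) -> dict[str, Repertoire]:
    """One repertoire of the given kind per individual in a tidy transcript table."""
    if kind not in ("syllable", "sequence"):
        raise ValueError(f"kind must be 'syllable' or 'sequence', got {kind!r}")
    out = {}
    for ind, sub in transcripts.groupby("individual_id", sort=True):
        if kind == "syllable":
            out[str(ind)] = syllable_repertoire(sub)
        else:
            out[str(ind)] = sequence_repertoire(sub, n_min, n_max)
    return out


def category_rs_table(
    focal_ids: Iterable[str],
    partner_map: Mapping[str, Mapping[str, str]],
    repertoires: Mapping[str, Repertoire],
) -> pd.DataFrame:
    """RS of each focal individual with its aN / dN / S partner.

    ``partner_map`` maps focal id -> {category: partner id}.  Returns a long
    table (focal_id, category, kind, partner_id, RS); summarize with
    :func:`category_summary`.
    """
    rows = []
    for focal in focal_ids:
        if focal not in repertoires:
            raise KeyError(f"no repertoire for focal individual {focal!r}")
        partners = partner_map[focal]
        for cat in CATEGORIES:
            if cat not in partners:
                raise KeyError(f"focal {focal!r} has no {cat!r} partner")
            pid = partners[cat]
            if pid not in repertoires:
                raise KeyError(
                    f"no repertoire for {cat!r} partner {pid!r} of focal {focal!r}"
                )
            rs = repertoire_similarity(repertoires[focal], repertoires[pid])
            rows.append(
                {
                    "focal_id": focal,
                    "category": cat,
                    "kind": repertoires[focal].kind,
                    "partner_id": pid,
                    "RS": rs.RS,
                }
            )
    return pd.DataFrame(rows, columns=["focal_id", "category", "kind",
                                       "partner_id", "RS"])


def category_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean RS with standard error per category (and kind)."""
    g = table.groupby(["kind", "category"])["RS"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
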