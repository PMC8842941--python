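"""Annotation data model for slide objects.

An annotation marks one α-synuclein-immunopositive object on a slide.
Foreground objects are Lewy-type synucleinopathy (LTS) — neurite-like
profiles — and carry a confidence rank reflecting annotator certainty:
``definite`` (3), ``probable`` (2) or ``possible`` (1).  Other
immunopositive structures (granules, macrophages, artifacts) are
``background`` and carry no rank.  Objects replayed from earlier
false-positive detections keep a distinct ``source`` so the detector can
weight them separately.

Annotations are serialized as GeoJSON FeatureCollections with polygon
coordinates in pixel units (x = column, y = row) and ``class``/``rank``
feature properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ValidationError

FOREGROUND = "foreground"
BACKGROUND = "background"


class Rank(IntEnum):
    """Annotator confidence rank for a foreground LTS object."""

    POSSIBLE = 1
    PROBABLE = 2
    DEFINITE = 3


#: Loss weight assigned to a training patch by the rank of the most
#: confident foreground object it contains; false-positive replays get 2
#: and patches with no foreground object get 1.
RANK_LOSS_WEIGHT = {Rank.DEFINITE: 5, Rank.PROBABLE: 4, Rank.POSSIBLE: 3}
FALSE_POSITIVE_WEIGHT = 2
NEGATIVE_WEIGHT = 1


@dataclass(frozen=True)
class AnnotationObject:
    """A polygonal or point object on a slide.

    Parameters
    ----------
    geometry
        Shapely geometry in pixel coordinates (x = column, y = row).
    object_class
        ``"foreground"`` (an LTS object) or ``"background"``.
    rank
        Confidence rank; required iff the object is foreground.
    source
        ``"human"`` for annotator-drawn objects, ``"false_positive_replay"``
        for objects replayed from an earlier detector round.
    """

    geometry: BaseGeometry
    object_class: str
    rank: Rank | None = None
    source: str = "human"

    def __post_init__(self) -> None:
        if self.object_class not in (FOREGROUND, BACKGROUND):
            raise ValidationError(f"unknown object class {self.object_class!r}")
        if self.object_class == FOREGROUND and self.rank is None:
            raise ValidationError("foreground objects require a confidence rank")
        if self.object_class == BACKGROUND and self.rank is not None:
            raise ValidationError("background objects carry no rank")
        if self.source not in ("human", "false_positive_replay"):
            raise ValidationError(f"unknown source {self.source!r}")

    @property
    def is_foreground(self) -> bool:
        return self.object_class == FOREGROUND

    def loss_weight(self) -> int:
        """Training weight contributed by this object to a patch."""
        if self.source == "false_positive_replay":
            return FALSE_POSITIVE_WEIGHT
        if self.is_foreground:
            return RANK_LOSS_WEIGHT[Rank(self.rank)]
        return NEGATIVE_WEIGHT


def exclude_rank(
    annotations: Iterable[AnnotationObject], rank: Rank | int | str
) -> list[AnnotationObject]:
    """Drop every foreground object of the named rank.

    Mirrors the concordance analysis in which ambiguous (``possible``)
    objects are removed before recomputing agreement.
    """
    rank = _coerce_rank(rank)
    return [a for a in annotations if a.rank != rank]


def _coerce_rank(rank: Rank | int | str) -> Rank:
    if isinstance(rank, str):
        try:
            return Rank[rank.upper()]
        except KeyError:
            raise ValidationError(f"unknown rank {rank!r}") from None
    try:
        return Rank(rank)
    except ValueError:
        raise ValidationError(f"unknown rank {rank!r}") from None


def to_geojson(annotations: Sequence[AnnotationObject]) -> dict:
    """Serialize annotations to a GeoJSON FeatureCollection dict."""
    features = []
    for a in annotations:
        props = {"class": a.object_class, "source": a.source}
        if a.rank is not None:
            props["rank"] = Rank(a.rank).name.lower()
        features.append(
            {"type": "Feature", "geometry": mapping(a.geometry), "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}


def from_geojson(doc: dict) -> list[AnnotationObject]:
    """Parse a FeatureCollection produced by :func:`to_geojson`."""
    out = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        rank = props.get("rank")
        out.append(
            AnnotationObject(
                geometry=shape(feat["geometry"]),
                object_class=props["class"],
                rank=_coerce_rank(rank) if rank is not None else None,
                source=props.get("source", "human"),
            )
        )
    return out


def write_geojson(annotations: Sequence[AnnotationObject], path) -> None:
    with open(path, "w") as fh:
        json.dump(to_geojson(annotations), fh)


def read_geojson(path) -> list[AnnotationObject]:
    with open(path) as fh:
        return from_geojson(json.load(fh))
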