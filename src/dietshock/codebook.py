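"""Food-group codebook: survey groups, score-group mappings, site masks.

The codebook is the single source of truth for the 20 survey food groups,
their mapping onto the 10 dietary-diversity (MDD-W) groups and the 20
diet-quality (PDQS) groups (with healthy/unhealthy flags), and per-site
exclusion masks.  It ships as a packaged, editable YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

#: The ten dietary-diversity groups, in canonical order.
MDDW_GROUPS: tuple[str, ...] = (
    "grains_roots_tubers",
    "legumes",
    "nuts_seeds",
    "dairy",
    "meat_poultry_fish",
    "eggs",
    "vitamin_a_dark_green_vegetables",
    "other_vitamin_a_fruits_vegetables",
    "other_vegetables",
    "other_fruits",
)

N_HEALTHY = 14
N_UNHEALTHY = 6


class CodebookError(ValueError):
    """Raised when a codebook violates its structural invariants."""


@dataclass(frozen=True)
class FoodGroup:
    """One survey food group and its score-group destinations."""

    id: str
    label: str
    mddw_group: str | None  # None: not counted toward dietary diversity
    healthy: bool  # PDQS healthy/unhealthy flag


@dataclass(frozen=True)
class Codebook:
    version: int
    note: str
    groups: tuple[FoodGroup, ...]
    site_masks: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        # caches (frozen dataclass, hence object.__setattr__)
        object.__setattr__(self, "_by_id", {g.id: g for g in self.groups})
        object.__setattr__(self, "_mddw_constituents", self._build_constituents())

    # -- structural invariants -------------------------------------------

    def validate(self) -> None:
        ids = [g.id for g in self.groups]
        if len(ids) != len(set(ids)):
            raise CodebookError("duplicate survey food-group ids")
        if len(ids) != 20:
            raise CodebookError(f"expected 20 survey food groups, got {len(ids)}")
        n_healthy = sum(g.healthy for g in self.groups)
        if n_healthy != N_HEALTHY:
            raise CodebookError(
                f"expected {N_HEALTHY} healthy groups, got {n_healthy}"
            )
        for g in self.groups:
            if g.mddw_group is not None and g.mddw_group not in MDDW_GROUPS:
                raise CodebookError(
                    f"group {g.id!r} maps to unknown MDD-W group {g.mddw_group!r}"
                )
        known = set(ids)
        for site, mask in self.site_masks.items():
            unknown = mask - known
            if unknown:
                raise CodebookError(
                    f"site mask for {site!r} references unknown groups: {sorted(unknown)}"
                )

    # -- lookups ----------------------------------------------------------

    @property
    def survey_group_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.groups)

    @property
    def healthy_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.groups if g.healthy)

    @property
    def unhealthy_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.groups if not g.healthy)

    def group(self, group_id: str) -> FoodGroup:
        try:
            return self._by_id[group_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(group_id) from None

    def _build_constituents(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {m: [] for m in MDDW_GROUPS}
        for g in self.groups:
            if g.mddw_group is not None:
                out[g.mddw_group].append(g.id)
        return {m: tuple(v) for m, v in out.items()}

    def mddw_constituents(self) -> dict[str, tuple[str, ...]]:
        """MDD-W group id -> survey group ids feeding it."""
        return self._mddw_constituents  # type: ignore[attr-defined]

    def mask_for_site(self, site: str) -> frozenset[str]:
        """Survey group ids excluded at *site* (empty set when unmasked)."""
        return self.site_masks.get(site, frozenset())

    def mddw_mask_for_site(self, site: str) -> frozenset[str]:
        """MDD-W groups masked at *site*: all constituents must be masked."""
        masked = self.mask_for_site(site)
        out = set()
        for mddw_id, constituents in self.mddw_constituents().items():
            if constituents and all(c in masked for c in constituents):
                out.add(mddw_id)
        return frozenset(out)


def _parse(raw: dict) -> Codebook:
    try:
        groups = tuple(
            FoodGroup(
                id=g["id"],
                label=g.get("label", g["id"]),
                mddw_group=g.get("mddw_group"),
                healthy=bool(g["healthy"]),
            )
            for g in raw["groups"]
        )
    except (KeyError, TypeError) as exc:
        raise CodebookError(f"malformed codebook: {exc}") from exc
    masks = {
        site: frozenset(ids) for site, ids in (raw.get("site_masks") or {}).items()
    }
    return Codebook(
        version=int(raw.get("version", 0)),
        note=str(raw.get("note", "")),
        groups=groups,
        site_masks=masks,
    )


def load_codebook(path: str | Path | None = None) -> Codebook:
    """Load a codebook YAML; default is the packaged reconstruction."""
    if path is None:
        text = (
            resources.files("dietshock").joinpath("data/codebook.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return _parse(yaml.safe_load(text))
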