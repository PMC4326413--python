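"""Risk presentations: pictograph, clustered bar graph, flowchart + stacked bars.

All presentations are derived from the same prediction and share exact
"out of 100 patients" natural frequencies computed by largest-remainder
rounding (floor each quota, then hand the shortfall to the largest fractional
remainders; ties broken by the fixed category order independent → dependent →
dead).  In the treated pictograph panel, icons attributable to the SICH branch
carry the letter H; their per-category allocation follows the same rounding
rule applied to p_sich × post-SICH proportions, nested inside the category
blocks so both the outcome totals and the SICH count are preserved.

Renderers are deterministic: the same presentation always yields byte-identical
SVG 1.1 or plain-text output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CATEGORY_ORDER",
    "COLOUR_TOKENS",
    "FrequencySet",
    "Icon",
    "Panel",
    "PresentationSpec",
    "to_frequencies",
    "largest_remainder",
    "frequency_set",
    "build_pictograph",
    "build_clustered_bar",
    "build_flowchart_stacked",
    "summary_box",
    "render",
]

CATEGORY_ORDER = ("independent", "dependent", "dead")

#: Colour tokens, configurable; green marks the positive outcome
#: ("green's for go"), a dark token marks death.
COLOUR_TOKENS = {
    "independent": "#2e8b57",
    "dependent": "#e8a33d",
    "dead": "#4a4a4a",
    "sich": "#b03030",
}

_TEXT_GLYPHS = {"independent": "I", "dependent": "D", "dead": "X"}


# ---------------------------------------------------------------------------
# Natural frequencies
# ---------------------------------------------------------------------------

def largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer units to ``weights`` by largest remainder.

    Quotas are weights/sum(weights)*total; each gets its floor, and the
    shortfall goes one unit at a time to the largest fractional remainders,
    ties resolved by position (earlier category wins).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    s = float(sum(weights))
    if s <= 0.0:
        counts = [0] * len(weights)
        if total and weights:
            counts[0] = total
        return counts
    quotas = [w / s * total for w in weights]
    counts = [int(q) for q in quotas]
    shortfall = total - sum(counts)
    remainders = sorted(
        range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def to_frequencies(dist: Sequence[float], denominator: int = 100) -> tuple[int, ...]:
    """Exact integer natural frequencies for a probability vector.

    Counts sum to ``denominator`` exactly; per-category error versus the
    unrounded expectation is below one unit.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if any(p < -1e-12 for p in dist):
        raise ValueError("probabilities must be non-negative")
    return tuple(largest_remainder([max(p, 0.0) for p in dist], denominator))


@dataclass(frozen=True)
class FrequencySet:
    """Integer counts per category per arm, plus the treated-arm SICH count."""

    untreated: dict
    treated: dict
    sich: int
    denominator: int = 100

    def __post_init__(self):
        for arm_counts in (self.untreated, self.treated):
            if any(c < 0 for c in arm_counts.values()):
                raise ValueError("counts must be non-negative")
            if sum(arm_counts.values()) != self.denominator:
                raise ValueError("per-arm counts must sum exactly to the denominator")
        if not (0 <= self.sich <= self.denominator):
            raise ValueError("SICH count must lie within the denominator")


def frequency_set(pred) -> FrequencySet:
    """Recompute the exact per-100 counts from a prediction's distributions."""
    denom = pred.frequencies.get("denominator", 100) if pred.frequencies else 100
    unt = to_frequencies(pred.untreated.as_tuple(), denom)
    tre = to_frequencies(pred.treated.as_tuple(), denom)
    sich = to_frequencies((pred.p_sich, 1.0 - pred.p_sich), denom)[0]
    return FrequencySet(
        untreated=dict(zip(CATEGORY_ORDER, unt)),
        treated=dict(zip(CATEGORY_ORDER, tre)),
        sich=sich,
        denominator=denom,
    )


# ---------------------------------------------------------------------------
# Presentation layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Icon:
    category: str
    sich: bool = False


@dataclass(frozen=True)
class Panel:
    arm: str
    title: str
    counts: dict
    icons: tuple[Icon, ...] = ()
    segments: tuple = ()     # (category, count) for bar/stacked layouts
    sich_count: int = 0


@dataclass(frozen=True)
class PresentationSpec:
    kind: str                              # pictograph | clustered_bar | flowchart_stacked
    panels: tuple[Panel, ...]              # (untreated, treated) juxtaposed
    category_order: tuple[str, ...]
    colours: dict
    captions: tuple[str, ...]
    summary: str
    denominator: int = 100

    def __post_init__(self):
        if tuple(self.category_order) != CATEGORY_ORDER:
            raise ValueError("category order must be (independent, dependent, dead)")


def _sich_allocation(freqs: FrequencySet, post_sich_tuple: Sequence[float]) -> dict:
    """Allocate the SICH count across treated categories.

    Weights are the post-SICH proportions (the mixture's SICH branch); the
    allocation is rounded by largest remainder to the exact SICH count, then
    clamped so no category carries more H icons than it has icons, with any
    overflow redistributed to categories that still have room.
    """
    alloc = largest_remainder(list(post_sich_tuple), freqs.sich)
    counts = [freqs.treated[c] for c in CATEGORY_ORDER]
    clamped = [min(a, c) for a, c in zip(alloc, counts)]
    overflow = sum(alloc) - sum(clamped)
    for i in range(len(clamped)):
        if overflow == 0:
            break
        room = counts[i] - clamped[i]
        take = min(room, overflow)
        clamped[i] += take
        overflow -= take
    return dict(zip(CATEGORY_ORDER, clamped))


def build_pictograph(pred, post_sich=None) -> PresentationSpec:
    """Two 10×10 icon grids (untreated, treated) in reading order.

    Icons are grouped by category in the fixed order; within each treated
    category block the H-marked (SICH-attributable) icons come last.
    ``post_sich`` (the post-SICH outcome distribution) weights the H
    allocation; when omitted, H icons all mark the treated dead block if
    possible, falling back to available room.
    """
    freqs = frequency_set(pred)
    if post_sich is not None:
        weights = post_sich.as_tuple()
    else:
        weights = tuple(getattr(pred, "post_sich", (0.0, 0.0, 1.0)))
    h_alloc = _sich_allocation(freqs, weights)

    panels = []
    for arm in ("untreated", "treated"):
        counts = getattr(freqs, arm)
        icons: list[Icon] = []
        for cat in CATEGORY_ORDER:
            n = counts[cat]
            h = h_alloc[cat] if arm == "treated" else 0
            icons.extend(Icon(cat) for _ in range(n - h))
            icons.extend(Icon(cat, sich=True) for _ in range(h))
        panels.append(
            Panel(
                arm=arm,
                title=f"Without treatment ({pred.time_horizon_label})"
                if arm == "untreated"
                else f"With clot-busting treatment ({pred.time_horizon_label})",
                counts=dict(counts),
                icons=tuple(icons),
                sich_count=freqs.sich if arm == "treated" else 0,
            )
        )

    captions = (
        f"Out of 100 patients, at {pred.time_horizon_label}.",
        f"H marks symptomatic intracranial haemorrhage (SICH) and its impact, "
        f"{pred.sich_horizon_label}.",
        "Please note: predicted clinical outcomes at 3 months apply to patients "
        "with pre-stroke modified Rankin scores of 0 to 2",
    )
    return PresentationSpec(
        kind="pictograph",
        panels=tuple(panels),
        category_order=CATEGORY_ORDER,
        colours=dict(COLOUR_TOKENS),
        captions=captions,
        summary=summary_box(pred),
    )


def build_clustered_bar(pred) -> PresentationSpec:
    """Paired bars per category, arms side-by-side, percentage axis."""
    panels = []
    for arm, dist in (("untreated", pred.untreated), ("treated", pred.treated)):
        percents = dict(zip(CATEGORY_ORDER, (round(p * 100, 1) for p in dist.as_tuple())))
        panels.append(
            Panel(
                arm=arm,
                title="Without treatment" if arm == "untreated" else "With treatment",
                counts=percents,
                segments=tuple((c, percents[c]) for c in CATEGORY_ORDER),
            )
        )
    return PresentationSpec(
        kind="clustered_bar",
        panels=tuple(panels),
        category_order=CATEGORY_ORDER,
        colours=dict(COLOUR_TOKENS),
        captions=(f"Predicted clinical outcomes at {pred.time_horizon_label} (%).",),
        summary=summary_box(pred),
    )


def build_flowchart_stacked(pred) -> PresentationSpec:
    """Treatment branch → SICH / no-SICH sub-branches → stacked outcome bars."""
    freqs = frequency_set(pred)
    panels = []
    for arm in ("untreated", "treated"):
        counts = getattr(freqs, arm)
        panels.append(
            Panel(
                arm=arm,
                title="Without treatment" if arm == "untreated" else "With treatment",
                counts=dict(counts),
                segments=tuple((c, counts[c]) for c in CATEGORY_ORDER),
                sich_count=freqs.sich if arm == "treated" else 0,
            )
        )
    captions = (
        f"Out of 100 patients treated, {freqs.sich} per 100 suffer SICH "
        f"({pred.sich_horizon_label}); {100 - freqs.sich} per 100 do not.",
        f"Stacked bars show outcomes at {pred.time_horizon_label}; "
        "segments per bar sum to 100%.",
    )
    return PresentationSpec(
        kind="flowchart_stacked",
        panels=tuple(panels),
        category_order=CATEGORY_ORDER,
        colours=dict(COLOUR_TOKENS),
        captions=captions,
        summary=summary_box(pred),
    )


def summary_box(pred) -> str:
    """One-sentence natural-frequency statement of net benefit and mortality."""
    freqs = frequency_set(pred)
    diff_ind = freqs.treated["independent"] - freqs.untreated["independent"]
    diff_dead = freqs.treated["dead"] - freqs.untreated["dead"]

    if diff_ind > 0:
        benefit = (
            f"Out of 100 patients, {diff_ind} more would be independent at "
            f"{pred.time_horizon_label} with clot-busting treatment than without."
        )
    elif diff_ind < 0:
        benefit = (
            f"Out of 100 patients, {-diff_ind} fewer would be independent at "
            f"{pred.time_horizon_label} with clot-busting treatment than without."
        )
    else:
        benefit = (
            f"Out of 100 patients, the number independent at "
            f"{pred.time_horizon_label} is unchanged by clot-busting treatment."
        )

    if diff_dead == 0:
        mortality = "There is no change in risk of death."
    elif diff_dead > 0:
        mortality = f"{diff_dead} more per 100 would die with treatment."
    else:
        mortality = f"{-diff_dead} fewer per 100 would die with treatment."
    return f"{benefit} {mortality}"


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(presentation: PresentationSpec, format: str = "text") -> str:
    """Render a presentation deterministically to ``svg`` or ``text``."""
    if format == "text":
        return _render_text(presentation)
    if format == "svg":
        return _render_svg(presentation)
    raise ValueError(f"unknown render format {format!r} (use 'svg' or 'text')")


def _render_text(p: PresentationSpec) -> str:
    lines: list[str] = []
    if p.kind == "pictograph":
        for panel in p.panels:
            lines.append(panel.title)
            for row in range(10):
                chars = []
                for col in range(10):
                    icon = panel.icons[row * 10 + col]
                    chars.append("H" if icon.sich else _TEXT_GLYPHS[icon.category])
                lines.append("".join(chars))
            lines.append(
                "  ".join(f"{cat}: {panel.counts[cat]}" for cat in p.category_order)
            )
            lines.append("")
    elif p.kind == "clustered_bar":
        header = f"{'category':<12}" + "".join(f"{panel.title:>20}" for panel in p.panels)
        lines.append(header)
        for cat in p.category_order:
            lines.append(
                f"{cat:<12}"
                + "".join(f"{panel.counts[cat]:>19.1f}%" for panel in p.panels)
            )
        lines.append("")
    elif p.kind == "flowchart_stacked":
        for panel in p.panels:
            lines.append(panel.title)
            if panel.arm == "treated":
                lines.append(f"  SICH: {panel.sich_count} per 100")
                lines.append(f"  no SICH: {p.denominator - panel.sich_count} per 100")
            for cat, count in panel.segments:
                lines.append(f"    {cat}: {count} per 100")
            lines.append("")
    else:
        raise ValueError(f"unknown presentation kind {p.kind!r}")
    lines.extend(p.captions)
    lines.append(p.summary)
    return "\n".join(lines) + "\n"


_CELL = 22          # icon cell size, px
_ICON = 18          # icon square size, px
_PANEL_W = 10 * _CELL + 40
_PANEL_H = 10 * _CELL + 60


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _render_svg(p: PresentationSpec) -> str:
    width = 2 * _PANEL_W + 60
    height = _PANEL_H + 40 * (len(p.captions) + 1) + 40
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">',
    ]
    if p.kind == "pictograph":
        for pi, panel in enumerate(p.panels):
            x0 = 20 + pi * (_PANEL_W + 20)
            parts.append(
                f'<text x="{x0}" y="20" font-size="14" font-family="sans-serif">'
                f"{_esc(panel.title)}</text>"
            )
            for idx, icon in enumerate(panel.icons):
                row, col = divmod(idx, 10)
                x = x0 + col * _CELL
                y = 36 + row * _CELL
                fill = p.colours[icon.category]
                parts.append(
                    f'<rect x="{x}" y="{y}" width="{_ICON}" height="{_ICON}" '
                    f'fill="{fill}" stroke="#ffffff"/>'
                )
                if icon.sich:
                    parts.append(
                        f'<text x="{x + _ICON // 2}" y="{y + _ICON - 4}" '
                        f'font-size="13" font-family="sans-serif" font-weight="bold" '
                        f'fill="#ffffff" text-anchor="middle">H</text>'
                    )
    elif p.kind == "clustered_bar":
        bar_w, gap, scale = 40, 16, 2.0
        base_y = _PANEL_H
        for ci, cat in enumerate(p.category_order):
            for pi, panel in enumerate(p.panels):
                value = float(panel.counts[cat])
                h = value * scale
                x = 40 + ci * (2 * bar_w + 3 * gap) + pi * (bar_w + 4)
                opacity = 'opacity="0.6" ' if panel.arm == "untreated" else ""
                parts.append(
                    f'<rect x="{x}" y="{base_y - h:.1f}" width="{bar_w}" '
                    f'height="{h:.1f}" fill="{p.colours[cat]}" '
                    f'{opacity}stroke="#333333"/>'
                )
                parts.append(
                    f'<text x="{x + bar_w // 2}" y="{base_y - h - 4:.1f}" '
                    f'font-size="11" font-family="sans-serif" text-anchor="middle">'
                    f"{value:.1f}%</text>"
                )
            parts.append(
                f'<text x="{40 + ci * (2 * bar_w + 3 * gap) + bar_w}" '
                f'y="{base_y + 16}" font-size="12" font-family="sans-serif" '
                f'text-anchor="middle">{cat}</text>'
            )
    elif p.kind == "flowchart_stacked":
        bar_w, scale = 60, 2.0
        base_y = _PANEL_H
        for pi, panel in enumerate(p.panels):
            x0 = 60 + pi * (_PANEL_W + 20)
            parts.append(
                f'<text x="{x0}" y="20" font-size="14" font-family="sans-serif">'
                f"{_esc(panel.title)}</text>"
            )
            if panel.arm == "treated":
                parts.append(
                    f'<text x="{x0}" y="40" font-size="12" font-family="sans-serif">'
                    f"SICH: {panel.sich_count} per 100 / no SICH: "
                    f"{p.denominator - panel.sich_count} per 100</text>"
                )
            y = base_y
            for cat, count in panel.segments:
                h = float(count) * scale
                y -= h
                parts.append(
                    f'<rect x="{x0}" y="{y:.1f}" width="{bar_w}" height="{h:.1f}" '
                    f'fill="{p.colours[cat]}" stroke="#ffffff"/>'
                )
                parts.append(
                    f'<text x="{x0 + bar_w + 8}" y="{y + h / 2 + 4:.1f}" '
                    f'font-size="11" font-family="sans-serif">{cat}: {count}</text>'
                )
    else:
        raise ValueError(f"unknown presentation kind {p.kind!r}")

    y_text = _PANEL_H + 30
    for caption in p.captions:
        parts.append(
            f'<text x="20" y="{y_text}" font-size="12" font-family="sans-serif">'
            f"{_esc(caption)}</text>"
        )
        y_text += 40
    parts.append(
        f'<text x="20" y="{y_text}" font-size="13" font-family="sans-serif" '
        f'font-weight="bold">{_esc(p.summary)}</text>'
    )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
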