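"""Published survey counts for the E. coli microcin-prevalence analysis.

Per-habitat and per-phylogroup assembly totals from the Australian E. coli
isolate collection the pipeline was applied to, plus the headline survey
tallies. Per-category microcin-positive counts were not published, so the
habitat table carries totals only; statistics that need positives per
category must be computed on user data.
"""

from __future__ import annotations

from . import stats

__all__ = [
    "HABITAT_TOTALS",
    "PHYLOGROUP_TOTALS",
    "SURVEY",
    "habitat_count_table",
]

# assemblies per isolation habitat (seven sources; 11 further isolates had
# no habitat label and are excluded from habitat analyses)
HABITAT_TOTALS = {
    "human_extraintestinal": 104,
    "human_intestinal": 172,
    "human_fecal": 72,
    "nonhuman_mammal_fecal": 117,
    "bird_meat": 283,
    "bird_fecal": 185,
    "freshwater": 280,
}

# assemblies per E. coli phylogroup (all 1,224 assemblies)
PHYLOGROUP_TOTALS = {
    "A": 292,
    "B1": 278,
    "B2": 304,
    "C": 16,
    "D": 174,
    "E": 57,
    "F": 71,
    "G": 32,
}

# headline tallies of the survey
SURVEY = {
    "n_assemblies": 1224,
    "n_assemblies_with_hits": 288,
    "n_with_verified": 211,
    "n_with_novel": 113,
    "n_with_both": 36,
    "n_assemblies_habitat_known": 1213,
    "n_habitat_assemblies_with_hits": 284,
}


def habitat_count_table(positives: dict[str, int]) -> stats.CountTable:
    """Build a habitat CountTable given per-habitat positive counts."""
    cats = list(HABITAT_TOTALS)
    return stats.CountTable(
        categories=cats,
        totals=[HABITAT_TOTALS[c] for c in cats],
        positives=[positives[c] for c in cats],
    )
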