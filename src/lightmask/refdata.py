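"""Published summary inputs from the motivating barley light-quality study.

These are worked-example *inputs*, not outputs: the per-gene direction
triplets of the core DE intersection shared by the three genotypes, and the
per-genotype DE-count partitions before/after development masking. The
package's set-algebra operations recompute the derived quantities
(concordance counts, retained counts and percentages) from them.

Genotype keys use the package's sensitivity labels; the study cultivars map
as Esterel -> insensitive, Price -> intermediate, WA1614-95 -> sensitive.
Direction triplets are ordered (intermediate, sensitive, insensitive), with
"u"/"d" meaning up-/down-regulated under fluorescent light.
"""

from __future__ import annotations

#: Core DE intersection shared by all three genotypes (q < 0.01):
#: gene id -> directions in (intermediate, sensitive, insensitive).
CORE_INTERSECTION_DIRECTIONS: dict[str, tuple[str, str, str]] = {
    "HORVU0Hr1G003020.3": ("d", "d", "d"),
    "HORVU2Hr1G063800.7": ("d", "d", "d"),
    "HORVU2Hr1G063810.1": ("d", "d", "d"),
    "HORVU7Hr1G036130.1": ("u", "u", "u"),
    "HORVU7Hr1G083670.3": ("u", "u", "u"),
    "HORVU2Hr1G013400.32": ("d", "d", "d"),
    "HORVU4Hr1G090860.12": ("u", "u", "u"),
    "HORVU5Hr1G071940.2": ("u", "u", "u"),
    "HORVU2Hr1G024120.10": ("d", "d", "d"),
    "HORVU0Hr1G038850.2": ("u", "u", "u"),
    "HORVU3Hr1G111550.2": ("u", "u", "d"),
    "HORVU3Hr1G021880.1": ("d", "d", "d"),
    "HORVU3Hr1G087100.1": ("d", "d", "d"),
    "HORVU7Hr1G024610.1": ("d", "d", "d"),
    "HORVU5Hr1G029260.1": ("d", "d", "d"),
    "HORVU2Hr1G104580.2": ("u", "u", "u"),
    "HORVU1Hr1G076460.3": ("u", "u", "u"),
}

#: The one core-intersection gene whose direction disagrees between the
#: sensitive and insensitive genotypes.
DISCORDANT_CORE_GENE = "HORVU3Hr1G111550.2"

#: Within-genotype DE counts (q < 0.01) partitioned by the development mask:
#: per genotype, total DE and the development-attributed subset, overall and
#: split by direction under fluorescent light.
MASKING_COUNTS: dict[str, dict[str, int]] = {
    "G_insensitive": {
        "total": 931, "development": 809,
        "down_total": 708, "down_development": 671,
        "up_total": 223, "up_development": 138,
    },
    "G_intermediate": {
        "total": 779, "development": 324,
        "down_total": 344, "down_development": 143,
        "up_total": 435, "up_development": 181,
    },
    "G_sensitive": {
        "total": 1126, "development": 723,
        "down_total": 576, "down_development": 410,
        "up_total": 550, "up_development": 313,
    },
}

#: DE genes shared only by the two sensitive genotypes: all concordant,
#: 74 up- and 68 down-regulated under fluorescent light.
SENSITIVE_PAIR_REGION = {"n_up": 74, "n_down": 68}
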