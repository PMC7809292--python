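import pytest

from ylineage.haplotree import parse_haplotree


def variant_specs(start_pos, n, anc="A", der="G"):
    """n variant specs at consecutive positions from start_pos."""
    return ",".join(f"{p}:{anc}:{der}:S{p}" for p in range(start_pos, start_pos + n))


@pytest.fixture
def backbone_tree_text():
    """Three-node chain R-Y2632 -> R-Y2633 -> R-SUR51 with 1/1/17 variants."""
    return "\n".join(
        [
            f"R-Y2632\t-\t{variant_specs(100, 1)}",
            f"R-Y2633\tR-Y2632\t{variant_specs(200, 1)}",
            f"R-SUR51\tR-Y2633\t{variant_specs(300, 17)}",
        ]
    )


@pytest.fixture
def backbone_tree(backbone_tree_text):
    return parse_haplotree(backbone_tree_text)


# Published per-sample average X and Y chromosome coverages for the nine
# ancient individuals, with their expected sex classification.
TABLE1_COVERAGES = {
    "HU3B": (3.81, 4.33, "XY"),
    "HU3G": (5.36, 5.67, "XY"),
    "HU4H": (3.63, 3.09, "XY"),
    "HU52": (2.32, 2.18, "XY"),
    "HU53": (0.59, 0.44, "XY"),
    "HU54": (0.66, 0.55, "XY"),
    "HU55": (0.95, 0.80, "XY"),
    "HU109": (4.01, 0.06, "XX"),
    "HUAA": (0.18, 0.00, "XX"),
}

# Terminal Y (FamilyTree nomenclature) and mtDNA haplogroups for the same
# nine individuals; '-' marks female samples without a Y assignment.
TABLE2_PROFILES = {
    "HU3B": ("R-ARP", "H1b"),
    "HUAA": ("-", "H7b1"),
    "HU52": ("R-ARP", "T2b2b1"),
    "HU3G": ("J-ZS7626", "U5b2c"),
    "HU4H": ("R-PF6658", "U4a"),
    "HU53": ("E-BY4992", "H1c1"),
    "HU54": ("R-YP1626", "U4a2b"),
    "HU55": ("R-BY41605", "J1c3a"),
    "HU109": ("-", "H46"),
}
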