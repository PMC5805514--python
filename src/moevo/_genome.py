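"""Reference autosome lengths (GRCh37) used by the simulator and CNA metrics."""

# GRCh37 / hg19 autosome lengths in bp.
GRCH37_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}

AUTOSOMES: tuple[str, ...] = tuple(GRCH37_AUTOSOMES)

TOTAL_AUTOSOMAL_BP: int = sum(GRCH37_AUTOSOMES.values())


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name to the 'chr1' style."""
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        name = "chr" + name
    return "chr" + name[3:]


def is_sex_chrom(name: str) -> bool:
    tail = normalize_chrom(name)[3:].upper()
    return tail in {"X", "Y"}
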