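"""Canonical simulated study conditions for end-to-end evaluation.

``benchmark_genome_plan`` builds a 50 Mb four-chromosome genome carrying 30
planted rearrangements covering every base SV type and all eight insertion
sub-types, including two small (3-4 kb) deletions below the 10 kb library's
detection limit and one 50 kb deletion whose breakpoints are flanked by
1.5 kb unmappable tracts that 1 kb fragments cannot span.

``amplicon_genome_plan`` emulates a focally amplified rearrangement unit: one
dominant fusion carried by a 10-copy episome plus single-copy satellite
fusions linking amplified segments across three chromosomes.

The library configurations mirror the study design: a 10 kb library at 60x
physical coverage versus a 1 kb library at 8x (same order of sequencing
effort), both with 1% chimeric ligations and 5% PCR duplicates.
"""

from __future__ import annotations

from petsv.simulator import (
    BalancedTranslocation,
    Deletion,
    GenomePlan,
    Insertion,
    Inversion,
    IsolatedTranslocation,
    Segment,
    SimConfig,
    TandemDuplication,
    UnpairedInversion,
    plant_svs,
)

CHIMERA_RATE = 0.01
DUPLICATE_RATE = 0.05

#: spans of the small deletions below the 10 kb span-bound detection limit;
#: planted in triplicate because recovering any single junction at 8x physical
#: coverage with a count cutoff of 3 carries a small Poisson dropout risk
SMALL_DELETION_SPANS = (3_000, 3_500, 4_000)
#: length of the unmappable tracts flanking the masked deletion's breakpoints
MASKED_FLANK = 1_500


def benchmark_requests() -> list:
    """The 30 planted rearrangements of the benchmark genome."""
    return [
        # chr1: deletions (incl. two sub-limit ones and a repeat-flanked one)
        Deletion("chr1", 1_000_000, 1_050_000),
        Deletion("chr1", 2_000_000, 2_030_000),
        Deletion("chr1", 3_000_000, 3_100_000),
        Deletion("chr1", 4_000_000, 4_000_000 + SMALL_DELETION_SPANS[0]),
        Deletion("chr1", 5_000_000, 5_000_000 + SMALL_DELETION_SPANS[1]),
        # (the third small deletion sits on chr3)
        Deletion("chr1", 6_000_000, 6_050_000),  # masked flanks added by the plan
        TandemDuplication("chr1", 7_000_000, 7_040_000),
        Inversion("chr1", 9_000_000, 9_100_000),
        Inversion("chr1", 10_500_000, 10_580_000),
        Insertion(1, "chr1", 11_000_000, 11_004_000, "chr1", 11_500_000),
        Insertion(2, "chr1", 12_500_000, 12_504_000, "chr1", 12_000_000),
        Insertion(3, "chr1", 13_000_000, 13_004_000, "chr1", 13_500_000),
        Insertion(4, "chr1", 14_500_000, 14_504_000, "chr1", 14_000_000),
        Insertion(5, "chr1", 15_000_000, 15_004_000, "chr1", 15_500_000),
        Insertion(6, "chr1", 16_000_000, 16_004_000, "chr1", 16_500_000),
        UnpairedInversion("chr1", 17_500_000),
        # chr2
        Deletion("chr2", 1_000_000, 1_150_000),
        TandemDuplication("chr2", 2_000_000, 2_050_000),
        Inversion("chr2", 3_000_000, 3_120_000),
        Insertion(1, "chr2", 4_000_000, 4_005_000, "chr2", 4_500_000),
        Insertion(7, "chr2", 5_000_000, 5_004_000, "chr3", 5_000_000),
        Insertion(8, "chr2", 6_000_000, 6_004_000, "chr3", 6_000_000),
        TandemDuplication("chr2", 7_000_000, 7_035_000),
        IsolatedTranslocation("chr2", 9_000_000, "chr4", 6_000_000),
        # chr3
        Deletion("chr3", 1_000_000, 1_060_000),
        Inversion("chr3", 2_000_000, 2_090_000),
        Deletion("chr3", 3_000_000, 3_000_000 + SMALL_DELETION_SPANS[2]),
        TandemDuplication("chr3", 4_000_000, 4_030_000),
        BalancedTranslocation("chr3", 8_000_000, "chr4", 3_000_000),
        UnpairedInversion("chr3", 9_500_000),
    ]


def benchmark_genome_plan() -> GenomePlan:
    """50 Mb genome, 30 planted SVs, repeat stand-ins at one deletion."""
    plan = GenomePlan(chrom_lengths={
        "chr1": 18_000_000,
        "chr2": 14_000_000,
        "chr3": 10_000_000,
        "chr4": 8_000_000,
    })
    # unmappable tracts hugging both breakpoints of the chr1:6.00-6.05 Mb deletion
    plan.add_mask("chr1", 6_000_000 - MASKED_FLANK, 6_000_000)
    plan.add_mask("chr1", 6_050_000, 6_050_000 + MASKED_FLANK)
    plant_svs(plan, benchmark_requests())
    return plan


def benchmark_sim_config(preset: str, seed: int = 0) -> SimConfig:
    """Study-condition library: 10 kb at 60x or 1 kb at 8x physical coverage."""
    coverage = {"10kb": 60.0, "1kb": 8.0, "20kb": 60.0}[preset]
    return SimConfig.preset(preset, coverage=coverage, chimera_rate=CHIMERA_RATE,
                            duplicate_rate=DUPLICATE_RATE, seed=seed)


def small_deletion_events(plan: GenomePlan) -> list:
    """Planted deletions below 5 kb (the 1 kb-library-specific class)."""
    return [e for e in plan.truth.events
            if e.label == "deletion" and (e.primary.span or 0) < 5_000]


def masked_deletion_event(plan: GenomePlan):
    """The deletion whose breakpoint flanks are unmappable tracts."""
    masked_points = {pos for ivs in plan.masked.values() for iv in ivs for pos in iv}
    for event in plan.truth.events:
        if event.label != "deletion":
            continue
        if any(pos in masked_points for _, pos in event.primary.breakpoints):
            return event
    raise LookupError("no masked-flank deletion in this plan")


# ---------------------------------------------------------------------------
# amplicon study conditions


AMPLICON_DOMINANT_COPIES = 10


def amplicon_genome_plan() -> GenomePlan:
    """Three 5 Mb chromosomes plus amplicon episomes: a dominant fusion
    (chrA:1.2 Mb | chrB:2.0 Mb) at ten copies and two single-copy satellite
    fusions chaining amplified segments of chrB->chrC and chrC->chrA."""
    plan = GenomePlan(chrom_lengths={"chrA": 5_000_000, "chrB": 5_000_000,
                                     "chrC": 5_000_000})
    plan.add_donor_chromosome("amp_dominant", [
        Segment("chrA", 900_000, 1_200_000),
        Segment("chrB", 2_000_000, 2_300_000),
    ], copies=AMPLICON_DOMINANT_COPIES)
    plan.add_donor_chromosome("amp_satellite1", [
        Segment("chrB", 2_100_000, 2_300_000),
        Segment("chrC", 3_000_000, 3_200_000),
    ])
    plan.add_donor_chromosome("amp_satellite2", [
        Segment("chrC", 3_100_000, 3_300_000),
        Segment("chrA", 1_000_000, 1_200_000),
    ])
    plan.ensure_donor()
    return plan


#: the dominant fusion's reference coordinates (5' exit, 3' entry)
AMPLICON_DOMINANT_FUSION = (("chrA", 1_200_000), ("chrB", 2_000_000))


def amplicon_sim_config(seed: int = 0) -> SimConfig:
    return SimConfig.preset("10kb", coverage=30.0, chimera_rate=CHIMERA_RATE,
                            duplicate_rate=DUPLICATE_RATE, seed=seed)
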