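"""Shared builders: PET records and dPET clusters with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from petsv.clustering import Anchor, DPETCluster, predict_breakpoints
from petsv.pet_io import LibraryConfig, PETRecord, TagAlignment

TAG = 25


def make_pet(read_id="r1", c5="chr1", s5=1_000, st5="+", c3="chr1", s3=2_000,
             st3="+", tag=TAG, status="unclassified") -> PETRecord:
    return PETRecord(
        read_id=read_id,
        tag5=TagAlignment(c5, s5, s5 + tag, st5),
        tag3=TagAlignment(c3, s3, s3 + tag, st3),
        status=status,
    )


def make_cluster(tags5, tags3, chrom5="chr1", strand5="+", chrom3="chr1",
                 strand3="+", cid="C1") -> DPETCluster:
    """Cluster from explicit (start, end) member tag intervals per side."""
    starts5 = np.array([t[0] for t in tags5])
    ends5 = np.array([t[1] for t in tags5])
    starts3 = np.array([t[0] for t in tags3])
    ends3 = np.array([t[1] for t in tags3])
    cluster = DPETCluster(
        id=cid,
        anchor5=Anchor(chrom5, int(starts5.min()), int(ends5.max()), strand5, "5"),
        anchor3=Anchor(chrom3, int(starts3.min()), int(ends3.max()), strand3, "3"),
        members=tuple(f"{cid}_m{k}" for k in range(len(tags5))),
        starts5=starts5, ends5=ends5, starts3=starts3, ends3=ends3,
    )
    predict_breakpoints(cluster)
    return cluster


def cluster_for_fusion(exit_point, entry_point, cid="C1", members=3,
                       spacing=1_000) -> DPETCluster:
    """Cluster whose members span a fusion joining ``exit_point`` (5' side,
    (chrom, pos, strand)) to ``entry_point`` (3' side).

    Tags approach the fusion in reading direction: innermost tag edge sits
    exactly on the fusion coordinate, further members step away by ``spacing``.
    """
    c5, p5, s5 = exit_point
    c3, p3, s3 = entry_point
    if s5 == "+":  # tags left of the exit coordinate
        tags5 = [(p5 - TAG - k * spacing, p5 - k * spacing) for k in range(members)]
    else:  # reading leftward: tags right of the exit coordinate
        tags5 = [(p5 + k * spacing, p5 + TAG + k * spacing) for k in range(members)]
    if s3 == "+":  # tags right of the entry coordinate
        tags3 = [(p3 + k * spacing, p3 + TAG + k * spacing) for k in range(members)]
    else:
        tags3 = [(p3 - TAG - k * spacing, p3 - k * spacing) for k in range(members)]
    return make_cluster(tags5, tags3, chrom5=c5, strand5=s5, chrom3=c3,
                        strand3=s3, cid=cid)


@pytest.fixture
def config_10kb() -> LibraryConfig:
    return LibraryConfig.preset("10kb")


@pytest.fixture
def config_1kb() -> LibraryConfig:
    return LibraryConfig.preset("1kb")
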