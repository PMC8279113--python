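"""Shared fixtures: synthetic arches, frames, rigid motions, IGES builder."""

from __future__ import annotations

import numpy as np
import pytest

from orthotrig import ArchSpec, build_reference_frame, generate_arch
from orthotrig.geometry import RigidTransform


@pytest.fixture(scope="session")
def clean_spec() -> ArchSpec:
    return ArchSpec(noise_sd_mm=0.0)


@pytest.fixture(scope="session")
def clean_arch(clean_spec):
    return generate_arch(clean_spec)


@pytest.fixture(scope="session")
def frame(clean_arch):
    return build_reference_frame(clean_arch)


def random_rigid(rng: np.random.Generator, max_translation: float = 50.0) -> RigidTransform:
    """Uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.uniform(-max_translation, max_translation, 3))


def _iges_line(data: str, code: str, seq: int) -> str:
    return f"{data:<72.72s}{code}{seq:7d}"


def make_iges(
    points,
    labels=None,
    pdelim: str = ",",
    rdelim: str = ";",
    units_flag: int | None = 2,
    extra_entity: bool = False,
    terminate: bool = True,
    bad_coordinate: bool = False,
) -> str:
    """Hand-construct a minimal fixed-80-column IGES 5.x file.

    Each point becomes one Type-116 entity (two directory lines, one
    parameter line).  ``extra_entity`` prepends an unsupported Type-110
    line entity; ``bad_coordinate`` corrupts the first point's x field.
    """

    def holl(s: str) -> str:
        return f"{len(s)}H{s}"

    labels = labels or [""] * len(points)
    gfields = [holl(pdelim), holl(rdelim), holl("test"), holl("test.igs"),
               holl("orthotrig-test"), holl("0.1"), "32", "38", "6", "308",
               "15", holl("test")]
    gfields += [
        "1.0",
        str(units_flag) if units_flag is not None else "",
        holl("MM"),
        "1",
        "0.1",
        holl("20240101.000000"),
        "1e-6",
        "100.0",
        holl("tester"),
        holl("lab"),
        "11",
        "0",
    ]
    gtext = pdelim.join(gfields) + rdelim

    lines = [_iges_line("synthetic minimal IGES fixture", "S", 1)]
    gseq = 0
    for i in range(0, len(gtext), 72):
        gseq += 1
        lines.append(_iges_line(gtext[i : i + 72], "G", gseq))

    entities = []
    if extra_entity:
        entities.append((110, pdelim.join(["110", "0.", "0.", "0.", "1.", "1.", "1."]), ""))
    for p, label in zip(points, labels):
        fields = ["116"] + [repr(float(v)) for v in p]
        if bad_coordinate and not entities:
            fields[1] = "abc"
        entities.append((116, pdelim.join(fields), label))

    dlines, plines = [], []
    pseq = 0
    for etype, params, label in entities:
        de_seq = len(dlines) + 1
        record = params + rdelim
        start = pseq + 1
        for j in range(0, len(record), 64):
            pseq += 1
            plines.append(
                f"{record[j : j + 64]:<64.64s}{de_seq:8d}P{pseq:7d}"
            )
        count = pseq - start + 1
        dlines.append(
            _iges_line(f"{etype:8d}{start:8d}{0:8d}{0:8d}{0:8d}{0:8d}{0:8d}{0:8d}00000000", "D", de_seq)
        )
        dlines.append(
            _iges_line(
                f"{etype:8d}{0:8d}{0:8d}{count:8d}{0:8d}{'':8s}{'':8s}{label:>8.8s}{0:8d}",
                "D",
                de_seq + 1,
            )
        )
    lines += dlines + plines
    if terminate:
        lines.append(
            _iges_line(
                f"S{1:7d}G{gseq:7d}D{len(dlines):7d}P{pseq:7d}", "T", 1
            )
        )
    return "\n".join(lines) + "\n"
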