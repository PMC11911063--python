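import pytest

from vertemorph import (
    AnnotationRecord,
    Deformity,
    LandmarkSet,
    PhantomSpec,
    generate_phantom,
)


def rectangle_landmarks(
    x0: float = 0.0,
    y0: float = 0.0,
    width: float = 10.0,
    height: float = 10.0,
    level: str | None = None,
) -> LandmarkSet:
    """Axis-aligned rectangular vertebra with anterior at x0 (left)."""
    return LandmarkSet(
        AU=(x0, y0), AL=(x0, y0 + height),
        CU=(x0 + width / 2, y0), CL=(x0 + width / 2, y0 + height),
        PU=(x0 + width, y0), PL=(x0 + width, y0 + height),
        frame="image", level=level,
    )


@pytest.fixture(scope="session")
def wedge_phantom_spec() -> PhantomSpec:
    """Noise-free 14-vertebra phantom, one wedge at severity 0.4, plus a
    diaphragm confuser: the standard end-to-end scenario."""
    return PhantomSpec(
        deformities={"T8": Deformity("wedge", 0.4)},
        noise_sd=0.0,
        confusers=("diaphragm",),
        seed=7,
    )


@pytest.fixture(scope="session")
def wedge_phantom(wedge_phantom_spec):
    return generate_phantom(wedge_phantom_spec)


@pytest.fixture(scope="session")
def mixed_phantom():
    """Noise-free phantom with one deformity of each type."""
    return generate_phantom(
        PhantomSpec(
            deformities={
                "T7": Deformity("wedge", 0.25),
                "T11": Deformity("biconcave", 0.3),
                "L3": Deformity("crush", 0.35),
            },
            noise_sd=0.0,
            seed=11,
        )
    )


def truth_records(case, image_id: str = "img-0") -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            case_id="case-0",
            image_id=image_id,
            level=lm.level,
            evaluator="truth",
            landmarks=lm,
        )
        for lm in case.truth_landmarks
    ]
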