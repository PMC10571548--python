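import pytest

from pentrack import Box, Detection, FrameStream, ObjectClass


@pytest.fixture
def unit_box():
    return Box(0, 0, 10, 10)


def make_det(frame, x1, y1, x2, y2, score=0.9, cls=ObjectClass.PIG):
    return Detection(frame, Box(x1, y1, x2, y2), score, cls)


@pytest.fixture
def make_detection():
    return make_det


def make_fight_stream(frames, fps=25.0, box=(100, 100, 300, 260), score=0.9):
    dets = [
        Detection(f, Box(*box), score, ObjectClass.PIG_FIGHTING) for f in frames
    ]
    return FrameStream(dets, fps=fps)


@pytest.fixture
def fight_stream_factory():
    return make_fight_stream
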