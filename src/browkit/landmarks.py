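"""Face-landmark layout constants for the OpenPose 70-point face model.

The 70-point layout places the eyebrows at indices 17-26 (five points per
brow) and the top of the nose bridge at index 27.  Indices 17-21 run along
the subject's right eyebrow ending at its inner tip (21); indices 22-26 run
along the subject's left eyebrow starting at its inner tip (22).

Only the four eyebrow landmarks below and the nose-top landmark are consumed
by the feature pipeline; every downstream module imports them from here.
"""

N_FACE_POINTS = 70
N_HAND_POINTS = 21
# Body model: 25 points is the standard BODY_25 layout; some exports carry 24.
POSE_POINT_COUNTS = (25, 24)

NOSE_TOP = 27

# Inner (medial) eyebrow tips, raised by AU1 / lowered by AU4.
INTERNAL_RIGHT = 21
INTERNAL_LEFT = 22
# Outer (lateral) eyebrow points, raised by AU2.
EXTERNAL_RIGHT = 18
EXTERNAL_LEFT = 25

INTERNAL_IDS = (INTERNAL_RIGHT, INTERNAL_LEFT)
EXTERNAL_IDS = (EXTERNAL_RIGHT, EXTERNAL_LEFT)

# Wrist indices in the BODY_25 pose layout, used for the hand-activity
# diagnostic that motivates trimming video edges.
POSE_RIGHT_WRIST = 4
POSE_LEFT_WRIST = 7

# Pupil centres (indices 68/69 in the 70-point layout), used only by the
# optional inter-ocular normalization of eyebrow distances.
PUPIL_RIGHT = 68
PUPIL_LEFT = 69

assert len(set(INTERNAL_IDS + EXTERNAL_IDS + (NOSE_TOP,))) == 5
assert all(0 <= i < N_FACE_POINTS for i in INTERNAL_IDS + EXTERNAL_IDS + (NOSE_TOP,))
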