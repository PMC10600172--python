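# Versioned keypoint rosters for the dam (32 points) and for individual
# pups (9 points, nose to tail base).  Downstream feature code refers to
# the named groups, never to roster positions, so the roster can only be
# changed by issuing a new version.
version: "1"
dam:
  names:
    - nose
    - left_eye
    - right_eye
    - head_center
    - left_ear
    - right_ear
    - left_ear_tip
    - right_ear_tip
    - neck
    - back_1
    - back_2
    - back_3
    - back_4
    - back_5
    - back_6
    - back_7
    - back_8
    - chest
    - ventrum_1
    - ventrum_2
    - pelvis
    - left_shoulder
    - right_shoulder
    - left_front_paw
    - right_front_paw
    - left_hip
    - right_hip
    - left_hind_paw
    - right_hind_paw
    - tail_base
    - tail_mid
    - tail_tip
  groups:
    head_points: [nose, left_eye, right_eye, head_center]
    ear_points: [left_ear, right_ear, left_ear_tip, right_ear_tip]
    back_points: [back_1, back_2, back_3, back_4, back_5, back_6, back_7, back_8]
    ventrum_points: [chest, ventrum_1, ventrum_2, pelvis]
    limb_points:
      - left_shoulder
      - right_shoulder
      - left_front_paw
      - right_front_paw
      - left_hip
      - right_hip
      - left_hind_paw
      - right_hind_paw
    tail_points: [tail_base, tail_mid, tail_tip]
    body_points:
      - neck
      - back_1
      - back_2
      - back_3
      - back_4
      - back_5
      - back_6
      - back_7
      - back_8
      - chest
      - ventrum_1
      - ventrum_2
      - pelvis
      - tail_base
pup:
  names:
    - nose
    - head
    - left_ear
    - right_ear
    - shoulder
    - spine_1
    - spine_2
    - hip
    - tail_base
  groups: {}
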