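# Canonical 25-keypoint physiotherapy skeleton.
# oks_k: per-keypoint OKS falloff constants; COCO sigmas for the 17 analogous
# joints, extras mapped to the nearest anatomical analog (neck->shoulder,
# spine->hip, thumb/pinky->wrist, heel/toe->ankle).
keypoints:
  - {index: 0,  name: right eye,      side: right,  group: head,  oks_k: 0.025}
  - {index: 1,  name: nose,           side: center, group: head,  oks_k: 0.026}
  - {index: 2,  name: left eye,       side: left,   group: head,  oks_k: 0.025}
  - {index: 3,  name: neck,           side: center, group: torso, oks_k: 0.079}
  - {index: 4,  name: right shoulder, side: right,  group: arm,   oks_k: 0.079}
  - {index: 5,  name: right elbow,    side: right,  group: arm,   oks_k: 0.072}
  - {index: 6,  name: right wrist,    side: right,  group: arm,   oks_k: 0.062}
  - {index: 7,  name: right thumb,    side: right,  group: hand,  oks_k: 0.062}
  - {index: 8,  name: right pinky,    side: right,  group: hand,  oks_k: 0.062}
  - {index: 9,  name: left shoulder,  side: left,   group: arm,   oks_k: 0.079}
  - {index: 10, name: left elbow,     side: left,   group: arm,   oks_k: 0.072}
  - {index: 11, name: left wrist,     side: left,   group: arm,   oks_k: 0.062}
  - {index: 12, name: left pinky,     side: left,   group: hand,  oks_k: 0.062}
  - {index: 13, name: left thumb,     side: left,   group: hand,  oks_k: 0.062}
  - {index: 14, name: spine,          side: center, group: torso, oks_k: 0.107}
  - {index: 15, name: right hip,      side: right,  group: leg,   oks_k: 0.107}
  - {index: 16, name: left hip,       side: left,   group: leg,   oks_k: 0.107}
  - {index: 17, name: right knee,     side: right,  group: leg,   oks_k: 0.087}
  - {index: 18, name: right ankle,    side: right,  group: leg,   oks_k: 0.089}
  - {index: 19, name: right toe,      side: right,  group: foot,  oks_k: 0.089}
  - {index: 20, name: right heel,     side: right,  group: foot,  oks_k: 0.089}
  - {index: 21, name: left knee,      side: left,   group: leg,   oks_k: 0.087}
  - {index: 22, name: left ankle,     side: left,   group: leg,   oks_k: 0.089}
  - {index: 23, name: left heel,      side: left,   group: foot,  oks_k: 0.089}
  - {index: 24, name: left toe,       side: left,   group: foot,  oks_k: 0.089}
edges:
  - [1, 0]    # nose - right eye
  - [1, 2]    # nose - left eye
  - [1, 3]    # nose - neck
  - [3, 14]   # neck - spine
  - [3, 4]    # neck - right shoulder
  - [3, 9]    # neck - left shoulder
  - [4, 5]    # right shoulder - elbow
  - [5, 6]    # right elbow - wrist
  - [6, 7]    # right wrist - thumb
  - [6, 8]    # right wrist - pinky
  - [9, 10]   # left shoulder - elbow
  - [10, 11]  # left elbow - wrist
  - [11, 13]  # left wrist - thumb
  - [11, 12]  # left wrist - pinky
  - [14, 15]  # spine - right hip
  - [14, 16]  # spine - left hip
  - [15, 17]  # right hip - knee
  - [17, 18]  # right knee - ankle
  - [18, 19]  # right ankle - toe
  - [18, 20]  # right ankle - heel
  - [16, 21]  # left hip - knee
  - [21, 22]  # left knee - ankle
  - [22, 24]  # left ankle - toe
  - [22, 23]  # left ankle - heel
symmetry_pairs:  # (left index, right index)
  - [2, 0]
  - [9, 4]
  - [10, 5]
  - [11, 6]
  - [13, 7]
  - [12, 8]
  - [16, 15]
  - [21, 17]
  - [22, 18]
  - [24, 19]
  - [23, 20]
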