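# Canonical seated-child template pose: 17 body joints and 68 facial
# landmarks (dlib ordering) on a 1280x720 frame, camera above the screen.
image_size:
- 1280
- 720
desk_level_y: 470.0
joints:
  nose:
  - 640.0
  - 200.0
  left_eye:
  - 655.0
  - 188.0
  right_eye:
  - 625.0
  - 188.0
  left_ear:
  - 672.0
  - 196.0
  right_ear:
  - 608.0
  - 196.0
  left_mouth:
  - 652.0
  - 226.0
  right_mouth:
  - 628.0
  - 226.0
  head_top:
  - 640.0
  - 148.0
  neck:
  - 640.0
  - 262.0
  left_shoulder:
  - 702.0
  - 284.0
  right_shoulder:
  - 578.0
  - 284.0
  left_elbow:
  - 722.0
  - 366.0
  right_elbow:
  - 558.0
  - 366.0
  left_wrist:
  - 712.0
  - 434.0
  right_wrist:
  - 568.0
  - 434.0
  left_hip:
  - 682.0
  - 474.0
  right_hip:
  - 598.0
  - 474.0
face_landmarks:
- - 686.0
  - 197.0
- - 685.12
  - 208.71
- - 682.5
  - 219.96
- - 678.25
  - 230.33
- - 672.53
  - 239.43
- - 665.56
  - 246.89
- - 657.6
  - 252.43
- - 648.97
  - 255.85
- - 640.0
  - 257.0
- - 631.03
  - 255.85
- - 622.4
  - 252.43
- - 614.44
  - 246.89
- - 607.47
  - 239.43
- - 601.75
  - 230.33
- - 597.5
  - 219.96
- - 594.88
  - 208.71
- - 594.0
  - 197.0
- - 602.0
  - 177.0
- - 609.0
  - 174.88
- - 616.0
  - 174.0
- - 623.0
  - 174.88
- - 630.0
  - 177.0
- - 650.0
  - 177.0
- - 657.0
  - 174.88
- - 664.0
  - 174.0
- - 671.0
  - 174.88
- - 678.0
  - 177.0
- - 640.0
  - 189.0
- - 640.0
  - 197.0
- - 640.0
  - 205.0
- - 640.0
  - 213.0
- - 630.0
  - 221.0
- - 635.0
  - 221.0
- - 640.0
  - 221.0
- - 645.0
  - 221.0
- - 650.0
  - 221.0
- - 608.0
  - 193.0
- - 611.22
  - 189.82
- - 626.78
  - 189.82
- - 630.0
  - 193.0
- - 626.78
  - 196.18
- - 611.22
  - 196.18
- - 650.0
  - 193.0
- - 653.22
  - 189.82
- - 668.78
  - 189.82
- - 672.0
  - 193.0
- - 668.78
  - 196.18
- - 653.22
  - 196.18
- - 626.0
  - 238.0
- - 627.88
  - 234.5
- - 633.0
  - 231.94
- - 640.0
  - 231.0
- - 647.0
  - 231.94
- - 652.12
  - 234.5
- - 654.0
  - 238.0
- - 652.12
  - 241.5
- - 647.0
  - 244.06
- - 640.0
  - 245.0
- - 633.0
  - 244.06
- - 627.88
  - 241.5
- - 631.0
  - 238.0
- - 633.64
  - 235.88
- - 640.0
  - 235.0
- - 646.36
  - 235.88
- - 649.0
  - 238.0
- - 646.36
  - 240.12
- - 640.0
  - 241.0
- - 633.64
  - 240.12
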