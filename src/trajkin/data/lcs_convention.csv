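lcs_id,name,origin,long_from,long_to,ref_from,ref_to,ref2_from,ref2_to
1,pelvis,hip_center,hip_center,spine,hip_left,hip_right,,
2,thorax,spine,hip_center,shoulder_center,shoulder_left,shoulder_right,,
3,head,head,shoulder_center,head,shoulder_left,shoulder_right,,
4,shoulder_L,shoulder_left,shoulder_left,shoulder_center,hip_center,shoulder_center,shoulder_left,shoulder_right
5,shoulder_R,shoulder_right,shoulder_right,shoulder_center,hip_center,shoulder_center,shoulder_left,shoulder_right
6,hand_L,hand_left,hand_left,wrist_left,hip_center,shoulder_center,shoulder_left,shoulder_right
7,hand_R,hand_right,hand_right,wrist_right,hip_center,shoulder_center,shoulder_left,shoulder_right
8,hip_L,hip_left,hip_left,hip_center,hip_center,shoulder_center,,
9,hip_R,hip_right,hip_right,hip_center,hip_center,shoulder_center,,
10,knee_L,knee_left,knee_left,hip_left,hip_left,hip_right,,
11,knee_R,knee_right,knee_right,hip_right,hip_left,hip_right,,
12,ankle_L,ankle_left,ankle_left,knee_left,hip_left,hip_right,,
13,ankle_R,ankle_right,ankle_right,knee_right,hip_left,hip_right,,
14,clavicle_L,shoulder_center|shoulder_left,hip_center,shoulder_center,shoulder_left,shoulder_right,,
15,clavicle_R,shoulder_center|shoulder_right,hip_center,shoulder_center,shoulder_left,shoulder_right,,
16,elbow_L,elbow_left,elbow_left,shoulder_left,hip_center,shoulder_center,shoulder_left,shoulder_right
17,elbow_R,elbow_right,elbow_right,shoulder_right,hip_center,shoulder_center,shoulder_left,shoulder_right
18,wrist_L,wrist_left,wrist_left,elbow_left,hip_center,shoulder_center,shoulder_left,shoulder_right
19,wrist_R,wrist_right,wrist_right,elbow_right,hip_center,shoulder_center,shoulder_left,shoulder_right
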