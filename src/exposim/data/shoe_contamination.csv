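position,task_id,label
1,look,look at shoe
2,approach,stand within arm's reach of shoe
3,touch_table,touch the table next to the shoe
4,touch_lace,touch a shoelace with one finger
5,touch_side,touch the side of the shoe with one finger
6,hold_palm,rest a palm flat on the shoe
7,pick_up,pick the shoe up with both hands
8,hold_ten,hold the shoe for ten seconds
9,shoe_to_arm,touch shoe to forearm
10,shoe_to_face,touch shoe to face
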