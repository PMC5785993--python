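method,successes,total,last_follow_up_days
intra_luminal_seeding,3,15,45
intra_colonic_wall_injection,6,8,21
endoscopic_implantation,12,13,10
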