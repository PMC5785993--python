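mouse_id,group,day,grade,fluorescence_detected
c1,control,1,1,True
c1,control,2,1,True
c1,control,3,2,True
c1,control,4,2,True
c1,control,5,2,True
c1,control,6,3,True
c1,control,7,3,True
c2,control,1,1,True
c2,control,2,2,True
c2,control,3,2,True
c2,control,4,2,True
c2,control,5,3,True
c2,control,6,4,True
c2,control,7,4,True
c3,control,1,0,True
c3,control,2,1,True
c3,control,3,1,True
c3,control,4,2,True
c3,control,5,3,True
c3,control,6,4,True
c3,control,7,4,True
c4,control,1,1,True
c4,control,2,2,True
c4,control,3,2,True
c4,control,4,3,True
c4,control,5,4,True
c4,control,6,5,True
c4,control,7,5,True
t1,irradiated,1,0,True
t1,irradiated,2,0,True
t1,irradiated,3,1,True
t1,irradiated,4,1,True
t1,irradiated,5,1,True
t1,irradiated,6,1,True
t1,irradiated,7,2,True
t2,irradiated,1,0,True
t2,irradiated,2,1,True
t2,irradiated,3,1,True
t2,irradiated,4,1,True
t2,irradiated,5,1,True
t2,irradiated,6,1,True
t2,irradiated,7,2,True
t3,irradiated,1,0,True
t3,irradiated,2,0,True
t3,irradiated,3,1,True
t3,irradiated,4,1,True
t3,irradiated,5,2,True
t3,irradiated,6,2,True
t3,irradiated,7,3,True
t4,irradiated,1,0,True
t4,irradiated,2,1,True
t4,irradiated,3,1,True
t4,irradiated,4,2,True
t4,irradiated,5,2,True
t4,irradiated,6,2,True
t4,irradiated,7,3,True
t5,irradiated,1,1,True
t5,irradiated,2,1,True
t5,irradiated,3,1,True
t5,irradiated,4,2,True
t5,irradiated,5,2,True
t5,irradiated,6,2,True
t5,irradiated,7,3,True
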