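image,gt_od_x_min,gt_od_y_min,gt_od_x_max,gt_od_y_max,pred_od_x_min,pred_od_y_min,pred_od_x_max,pred_od_y_max,gt_oc_x_min,gt_oc_y_min,gt_oc_x_max,gt_oc_y_max,pred_oc_x_min,pred_oc_y_min,pred_oc_x_max,pred_oc_y_max,gt_od_radius,pred_od_radius,gt_oc_radius,pred_oc_radius,gt_ratio,pred_ratio,actual_class,predicted_class
1,186,209,259,292,190,209,270,291,195,214,251,280,201,217,258,280,41.5,41.1,33,31.5,0.8,0.8,1,1
2,195,214,251,280,201,217,258,280,254,239,286,271,245,237,285,281,33,31.5,16,21.9,0.5,0.6,0,1
3,254,239,286,271,245,237,285,281,231,236,275,277,231,234,276,282,16,21.9,22,24.4,0.6,0.6,1,1
4,231,236,275,277,231,234,276,282,253,237,300,281,250,240,291,282,22,24.4,23.5,20.6,0.7,0.5,1,0
5,253,237,300,281,250,240,291,282,227,239,267,276,222,238,263,279,23.5,20.6,20,20.7,0.6,0.6,1,1
6,227,239,267,276,222,238,263,279,228,239,275,291,223,242,277,295,20,20.7,26,26.9,0.6,0.6,1,1
7,228,239,275,291,223,242,277,295,223,251,269,297,223,252,266,295,26,26.9,23,21.6,0.5,0.5,0,0
8,223,251,269,297,223,252,266,295,200,228,285,315,205,234,278,314,23,21.6,43.5,40.1,0.8,0.8,1,1
9,200,228,285,315,205,234,278,314,200,216,285,304,203,219,280,301,43.5,40.1,44,41.1,0.8,0.7,1,1
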