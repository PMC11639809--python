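area,day,video_id,sheep_id,duration,rr_ref,rr_video
Area1,1,1,1,00:58:47,31.47,29.00
Area1,1,2,1,00:37:52,26.15,28.70
Area1,2,3,1,00:45:00,23.33,23.79
Area1,2,4,1,00:08:00,26.33,24.11
Area2,3,5,1,00:48:00,25.72,29.75
Area2,3,6,1,01:21:00,28.22,29.23
Area2,3,6,2,01:21:00,24.37,27.13
Area2,3,7,1,00:12:00,31.00,27.99
Area2,4,8,1,01:03:00,27.52,29.20
Area2,4,8,2,01:09:00,28.04,29.49
Area2,4,9,1,02:04:00,28.88,29.42
Area2,4,9,2,01:58:20,29.03,29.40
Area2,4,10,1,02:10:00,28.27,29.26
Area2,4,10,2,00:45:00,27.93,29.55
Area2,4,11,1,00:53:00,26.33,26.09
Area2,4,12,1,00:08:00,30.67,29.48
Area2,4,13,1,00:40:00,28.21,28.51
Area2,4,14,1,00:36:00,26.17,28.99
Area2,4,15,1,00:45:00,31.13,27.93
Area2,4,15,2,01:22:00,37.43,35.73
Area2,4,15,3,00:51:00,22.88,22.71
Area2,5,16,1,00:16:00,39.17,39.78
Area2,5,16,2,00:10:00,21.75,20.55
Area2,5,17,1,00:57:00,30.95,29.78
Area2,5,17,2,00:54:00,26.78,28.94
Area2,5,18,1,00:36:00,27.08,29.48
Area2,5,18,2,00:21:00,28.00,28.40
Area2,5,19,1,00:40:00,33.39,28.63
Area2,5,20,1,01:32:16,36.67,35.76
Area2,5,21,1,00:03:00,37.00,34.99
Area2,5,22,1,00:20:00,33.00,29.52
Area2,5,23,1,00:40:00,33.14,27.62
Area2,5,23,2,00:36:00,29.00,29.57
Area2,5,24,1,00:12:00,24.75,23.51
Area2,5,24,2,00:12:00,20.00,22.20
Area2,5,25,1,01:33:00,32.13,29.28
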