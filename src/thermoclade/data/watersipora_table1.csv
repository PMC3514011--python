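region,site,latitude,longitude,sst_c,phylogroup,count,source
w. US,Bremerton,47.5798,-122.6321,10.0,new_sp,12,this_study
w. US,Bodega Bay,38.00,-123.00,11.3,new_sp,1,ref25
w. US,Bodega Bay Harbor,38.3295,-123.0562,11.3,new_sp,16,this_study
w. US,Humboldt Harbor,40.8074,-124.1635,11.8,B,11,this_study
w. US,Humboldt Harbor,40.8074,-124.1635,11.8,new_sp,33,this_study
Europe,Plymouth,50.30,-4.14,13.0,A,1,ref26
Europe,Guernsey,49.50,-2.58,13.0,A,2,ref26
Europe,St Jacut,48.60,-2.15,13.0,A,4,ref26
w. US,Moss Landing Harbor,36.8051,-121.7852,13.0,A,25,this_study
w. US,Moss Landing Harbor,36.8051,-121.7852,13.0,new_sp,12,this_study
w. US,Morro Bay,35.37,-120.86,13.3,new_sp,1,ref25
w. US,Morro Bay,35.3707,-120.8585,13.3,new_sp,14,this_study
w. US,San Francisco Bay,37.91,-122.35,13.5,new_sp,1,ref25
w. US,San Francisco Richmond,37.9130,-122.3503,13.5,A,25,this_study
w. US,San Francisco Richmond,37.9130,-122.3503,13.5,B,1,this_study
w. US,San Francisco Richmond,37.9130,-122.3503,13.5,new_sp,1,this_study
w. US,San Francisco Oakland,37.8102,-122.3230,13.5,A,1,this_study
w. US,San Francisco Oakland,37.7845,-122.2676,13.5,A,4,this_study
Australia,Hobart,-43.00,147.28,14.0,A,2,ref23
Europe,Wellington,-41.00,174.78,14.2,A,4,ref23
w. US,Tomales Bay,38.1991,-122.9220,14.3,A,17,this_study
w. US,Ventura,34.17,-119.23,15.1,B,1,ref25
Australia,Melbourne,-38.00,144.82,15.1,A,7,ref23
w. US,Channel Islands Harbor,34.1666,-119.2250,15.1,A,13,this_study
w. US,Channel Islands Harbor,34.166,-119.2250,15.1,new_sp,1,this_study
w. US,Channel Islands Harbor,34.1666,-119.2250,15.1,B,3,this_study
w. US,Port Hueneme,34.1532,-119.2095,15.1,arcuata,3,this_study
w. US,Port Hueneme,34.1532,-119.2095,15.1,A,2,this_study
w. US,Port Hueneme,34.1532,-119.2095,15.1,new_sp,14,this_study
w. US,Marina Del Rey,33.9702,-118.4496,15.1,arcuata,8,this_study
w. US,Marina Del Rey,33.9702,-118.4496,15.1,A,3,this_study
w. US,Santa Barbara,34.4067,-119.6890,16.0,arcuata,19,this_study
w. US,Santa Barbara,34.4067,-119.6890,16.0,new_sp,1,this_study
Australia,Adelaide,-34.50,138.53,16.3,arcuata,12,ref23
Australia,Adelaide,-34.50,138.53,16.3,A,1,ref23
w. US,Oceanside,33.21,-117.40,17.1,arcuata,2,ref25
w. US,San Diego Shelter Island,32.71,-117.23,17.1,A,1,ref25
w. US,Oceanside,33.2121,-117.3954,17.1,arcuata,1,this_study
w. US,Oceanside,33.2121,-117.3954,17.1,A,12,this_study
w. US,Oceanside,33.2121,-117.3954,17.1,B,3,this_study
w. US,Mission Bay,32.7671,-117.2362,17.1,A,18,this_study
w. US,Mission Bay,32.7671,-117.2362,17.1,B,1,this_study
w. US,Long Beach Harbor,33.7655,-118.2528,17.3,A,17,this_study
w. US,Long Beach Harbor,33.7655,-118.2528,17.3,B,4,this_study
w. US,Huntington Harbor,33.7175,-118.0658,17.3,A,17,this_study
w. US,Dana Point Harbor,33.4591,-117.6992,17.4,A,8,this_study
w. US,Dana Point Harbor,33.4591,-117.6992,17.4,B,5,this_study
w. US,Dana Point Tijuana Est.,33.4614,-117.7146,17.5,A,3,this_study
w. US,Newport,33.6199,-117.8943,18.2,A,14,this_study
w. US,Newport,33.6199,-117.8943,18.2,B,1,this_study
n. Asia,Korea Namhae Sangju,34.71,127.99,20.0,A,1,ref37
n. Asia,Korea Namhae Sangju,34.71,127.99,20.0,new_sp,1,ref37
Australia,Sydney,-33.87,151.21,20.3,arcuata,17,ref23
Australia,Sydney,-33.87,151.21,20.3,A,6,ref23
Australia,Perth,-31.93,115.83,20.5,arcuata,10,ref23
Australia,Perth,-31.93,115.83,20.5,A,3,ref23
n. Asia,Qingdao,36.054,120.38,23.0,B,1,ref36
e. US,Florida,27.20,-80.22,25.0,subovoidea,4,ref23
Europe,O'ahu,21.00,-157.87,25.7,arcuata,12,ref23
Australia,Dampier,-20.66,116.71,26.0,subovoidea,4,ref23
Brazil,Rio De Janeiro,-23.81,-45.43,26.0,subovoidea,14,this_study
Australia,Cairns,-16.88,145.80,26.5,subovoidea,1,ref23
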